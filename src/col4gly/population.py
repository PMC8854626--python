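"""Observed vs expected non-collagenous boundary Gly variants in a population.

Under neutral mutation, the chance that a random Gly missense SNV hits a
non-collagenous boundary Gly rather than any other collagenous Gly is set
by the mutational opportunity of each codon: every possible single-base
missense change, weighted by a neighbour-dependent substitution-rate
model (transitions outpace transversions, and CpG-context transitions are
strongly elevated by methyl-cytosine deamination).  Comparing that
expectation with the proportion observed in a population database by an
exact binomial test asks whether boundary variants are over-represented
among standing variation — the signature of a milder, less-selected
class.  Carrier prevalence is computed from hemizygote / heterozygote /
homozygote counts with X-linked allele accounting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import binom

from .chain_model import ChainArchitecture, GlyPositionClass, classify_position, gly_positions
from .splice import near_splice_site
from .variants import GLY_CODONS, _translate

__all__ = [
    "RateTable",
    "AlleleRecord",
    "PrevalenceResult",
    "default_rate_table",
    "read_rate_table",
    "write_rate_table",
    "context_rate",
    "GlyMissenseSite",
    "enumerate_gly_missense",
    "expected_boundary_fraction",
    "symmetrize",
    "exact_binomial",
    "allele_total",
    "carrier_prevalence",
    "read_allele_table",
]

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class RateTable:
    """Relative substitution rates keyed by (left, ref, alt, right).

    Covers all 12 substitution types in all 16 flanking contexts; rates
    are dimensionless and strictly positive.  ``stranded`` records whether
    the table was declared strand-specific at load time (otherwise it has
    been symmetrized with its reverse complement).
    """

    rates: dict[tuple[str, str, str, str], float]
    stranded: bool = False

    def __post_init__(self) -> None:
        expected = 16 * 12
        if len(self.rates) != expected:
            raise ValueError(
                f"rate table must cover {expected} (left, ref, alt, right) "
                f"contexts, got {len(self.rates)}"
            )
        for key, rate in self.rates.items():
            if rate <= 0:
                raise ValueError(f"non-positive rate for context {key}")


def default_rate_table(
    transition_transversion_ratio: float = 4.0, cpg_transition_boost: float = 10.0
) -> RateTable:
    """Parametric neighbour-dependent rate model.

    Transitions run at ``transition_transversion_ratio`` times the
    transversion rate, and the deamination-driven transitions at CpG
    dinucleotides (C>T with a 3' G; equivalently G>A with a 5' C) are
    boosted ``cpg_transition_boost``-fold on top.  The defaults are
    field-standard germline estimates; any transcribed published table can
    be supplied through :func:`read_rate_table` instead.
    """
    rates: dict[tuple[str, str, str, str], float] = {}
    for left in BASES:
        for ref in BASES:
            for alt in BASES:
                if alt == ref:
                    continue
                for right in BASES:
                    rate = 1.0
                    if (ref, alt) in _TRANSITIONS:
                        rate = transition_transversion_ratio
                        if ref == "C" and alt == "T" and right == "G":
                            rate *= cpg_transition_boost
                        elif ref == "G" and alt == "A" and left == "C":
                            rate *= cpg_transition_boost
                    rates[(left, ref, alt, right)] = rate
    return RateTable(rates, stranded=False)


def _reverse_complement_key(key: tuple[str, str, str, str]) -> tuple[str, str, str, str]:
    left, ref, alt, right = key
    return (
        _COMPLEMENT[right],
        _COMPLEMENT[ref],
        _COMPLEMENT[alt],
        _COMPLEMENT[left],
    )


def symmetrize(table: RateTable) -> RateTable:
    """Average every context with its reverse complement."""
    rates = {
        key: 0.5 * (rate + table.rates[_reverse_complement_key(key)])
        for key, rate in table.rates.items()
    }
    return RateTable(rates, stranded=False)


def read_rate_table(path: str | Path) -> RateTable:
    """Read a tab-separated rate table: columns left, ref, alt, right, rate.

    '#' lines are comments; a ``#stranded`` directive suppresses the
    default strand symmetrization.
    """
    stranded = False
    rates: dict[tuple[str, str, str, str], float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.lstrip("#").strip().lower() == "stranded":
                stranded = True
            continue
        left, ref, alt, right, rate = line.split("\t")[:5]
        rates[(left.upper(), ref.upper(), alt.upper(), right.upper())] = float(rate)
    table = RateTable(rates, stranded=stranded)
    return table if stranded else symmetrize(table)


def write_rate_table(table: RateTable, path: str | Path, comment: str | None = None) -> None:
    lines = []
    if comment:
        lines.extend(f"# {text}" for text in comment.splitlines())
    if table.stranded:
        lines.append("#stranded")
    lines.append("#left\tref\talt\tright\trate")
    for (left, ref, alt, right), rate in sorted(table.rates.items()):
        lines.append(f"{left}\t{ref}\t{alt}\t{right}\t{float(rate)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def context_rate(table: RateTable, left: str, ref: str, alt: str, right: str) -> float:
    """Rate of ref>alt substitution between the given flanking bases."""
    for base in (left, ref, alt, right):
        if base not in BASES:
            raise ValueError(f"invalid base {base!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    key = (left, ref, alt, right)
    if key not in table.rates:
        raise KeyError(f"rate table lacks context {key}")
    return table.rates[key]


@dataclass(frozen=True)
class GlyMissenseSite:
    """One possible Gly missense SNV with its mutational opportunity."""

    residue_index: int
    cdna_position: int  # 1-based CDS coordinate of the substituted base
    ref_base: str
    alt_base: str
    alt_residue: str
    is_boundary: bool
    rate: float


def enumerate_gly_missense(
    arch: ChainArchitecture,
    cds: str,
    table: RateTable,
    exclude_splice: bool = False,
) -> list[GlyMissenseSite]:
    """Every single-base missense substitution in every collagenous Gly codon.

    Synonymous (Gly) and nonsense outcomes are dropped; each substitution
    carries its neighbour-dependent rate (flanking bases from the CDS; a
    sequence terminus falls back on the only adjacent base).  With
    ``exclude_splice`` set, substitutions within 3 bases of an internal
    splice junction are dropped (requires an exon map on ``arch``).
    """
    cds = cds.upper()
    if len(cds) != 3 * arch.length:
        raise ValueError(
            f"CDS length {len(cds)} does not equal 3 x chain length {arch.length}"
        )
    sites: list[GlyMissenseSite] = []
    for residue, _region, _ordinal in gly_positions(arch):
        codon_start = 3 * (residue - 1)  # 0-based
        codon = cds[codon_start : codon_start + 3]
        if codon not in GLY_CODONS:
            raise ValueError(
                f"CDS codon {codon!r} at residue {residue} is not a Gly codon; "
                "sequence and architecture disagree"
            )
        is_boundary = classify_position(arch, residue) is GlyPositionClass.NC_BOUNDARY
        for offset in range(3):
            position = codon_start + offset  # 0-based CDS index
            if exclude_splice and near_splice_site(arch, position + 1):
                continue
            ref = codon[offset]
            left = cds[position - 1] if position > 0 else cds[position + 1]
            right = cds[position + 1] if position < len(cds) - 1 else cds[position - 1]
            for alt in BASES:
                if alt == ref:
                    continue
                mutant = codon[:offset] + alt + codon[offset + 1 :]
                residue_out = _translate(mutant)
                if residue_out is None or residue_out == "Gly":
                    continue  # nonsense or synonymous
                sites.append(
                    GlyMissenseSite(
                        residue_index=residue,
                        cdna_position=position + 1,
                        ref_base=ref,
                        alt_base=alt,
                        alt_residue=residue_out,
                        is_boundary=is_boundary,
                        rate=context_rate(table, left, ref, alt, right),
                    )
                )
    return sites


def expected_boundary_fraction(
    arch: ChainArchitecture,
    cds: str,
    table: RateTable,
    exclude_splice: bool = False,
) -> float:
    """Expected share of Gly missense SNVs hitting boundary Gly residues.

    The rate mass of boundary-Gly missense substitutions over the mass on
    all collagenous Gly, from :func:`enumerate_gly_missense`.  Invariant
    to global rescaling of the rate table.
    """
    sites = enumerate_gly_missense(arch, cds, table, exclude_splice=exclude_splice)
    total_mass = sum(site.rate for site in sites)
    if total_mass == 0.0:
        raise ValueError("no missense substitutions enumerated")
    boundary_mass = sum(site.rate for site in sites if site.is_boundary)
    return boundary_mass / total_mass


def exact_binomial(k: int, n: int, p0: float, alternative: str = "greater") -> float:
    """Exact binomial tail probability of k successes in n trials at null p0.

    Direct summation of the binomial mass function: ``greater`` sums the
    upper tail from k, ``less`` the lower tail to k, and ``two_sided``
    the mass of every outcome no more probable than k (with a 1e-12
    relative tolerance on the mass comparison to absorb float noise).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"null proportion must be in (0, 1), got {p0}")
    pmf = binom.pmf(np.arange(n + 1), n, p0)
    if alternative == "greater":
        p_value = pmf[k:].sum()
    elif alternative == "less":
        p_value = pmf[: k + 1].sum()
    elif alternative == "two_sided":
        p_value = pmf[pmf <= pmf[k] * (1.0 + 1e-12)].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(1.0, p_value))


@dataclass(frozen=True)
class AlleleRecord:
    """Genotype counts for one variant in a population database (X-linked)."""

    variant_label: str
    hemizygote_count: int
    heterozygote_count: int
    homozygote_count: int

    def __post_init__(self) -> None:
        for count in (self.hemizygote_count, self.heterozygote_count, self.homozygote_count):
            if count < 0:
                raise ValueError(f"negative genotype count in {self.variant_label}")

    @property
    def total_alleles(self) -> int:
        return allele_total(
            self.hemizygote_count, self.heterozygote_count, self.homozygote_count
        )

    @property
    def carriers(self) -> int:
        """Individuals carrying the variant (homozygous females count once)."""
        return self.hemizygote_count + self.heterozygote_count + self.homozygote_count


def allele_total(hem: int, het: int, hom: int) -> int:
    """Total alleles under X-linked counting: hem + het + 2*hom."""
    if hem < 0 or het < 0 or hom < 0:
        raise ValueError("genotype counts must be non-negative")
    return hem + het + 2 * hom


@dataclass(frozen=True)
class PrevalenceResult:
    carrier_count: int
    population_size: int
    prevalence: float
    one_in: int | None

    def as_report(self) -> dict:
        return {
            "carriers": self.carrier_count,
            "population": self.population_size,
            "prevalence": self.prevalence,
            "one_in": self.one_in,
        }


def carrier_prevalence(
    records: list[AlleleRecord], population: tuple[int, int]
) -> PrevalenceResult:
    """Population prevalence of carrying any listed variant.

    Each homozygous female is one carrier individual; variants are summed
    under the rare-variant approximation (no co-occurrence).
    """
    male_total, female_total = population
    if male_total <= 0 or female_total <= 0:
        raise ValueError("population totals must be positive")
    carriers = sum(record.carriers for record in records)
    size = male_total + female_total
    if carriers > size:
        raise ValueError(f"{carriers} carriers exceed population of {size}")
    prevalence = carriers / size
    one_in = round(1.0 / prevalence) if prevalence > 0 else None
    return PrevalenceResult(carriers, size, prevalence, one_in)


def read_allele_table(path: str | Path) -> list[AlleleRecord]:
    """Read a tab-separated allele table: variant, hem, het, hom columns."""
    records = []
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.lower() for f in fields]
            continue
        row = dict(zip(header, fields))
        records.append(
            AlleleRecord(
                variant_label=row["variant"],
                hemizygote_count=int(row["hem"]),
                heterozygote_count=int(row["het"]),
                homozygote_count=int(row["hom"]),
            )
        )
    if header is None:
        raise ValueError(f"empty allele table {path}")
    return records
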