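"""Synthetic cohorts with known ground truth for every pipeline stage.

The real study cohorts (a locus-specific family registry, a national
case-control genomes programme, and a population allele-frequency
database) cannot be redistributed, so this module generates stand-ins
whose *generating parameters are the study's own reported conditions*:

* architectures with 23 local collagenous regions (collagen IV alpha
  chains carry 21-26 non-collagenous interruptions) sized so boundary Gly
  make up about one tenth of collagenous Gly residues;
* family registries under an exponential proportional-hazards model with
  a reference median age at kidney failure of 26 years and hazard-ratio
  directions matching the survival analysis (boundary protective,
  highly destabilising residue harmful);
* case-control cohorts under a logistic model with intercept -2.41,
  boundary effect -1.25, high-destabilisation effect 0.94 and molecular
  location effect 0.24, boundary carriers ~15% of individuals;
* allele tables sampled proportional to neighbour-dependent mutational
  opportunity over a synthetic CDS.

Every generator is a pure function of its config and seed: identical
inputs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain_model import (
    ChainArchitecture,
    GlyPositionClass,
    build_architecture,
    classify_position,
    gly_positions,
)
from .population import AlleleRecord, RateTable, enumerate_gly_missense
from .survival import IndividualRecord
from .variants import GLY_CODONS, ProteinVariant, _translate, annotate

__all__ = [
    "ArchitectureConfig",
    "SurvivalGenConfig",
    "LogisticGenConfig",
    "AlleleGenConfig",
    "SpliceGenConfig",
    "gen_architecture",
    "gen_cds",
    "gen_registry",
    "gen_cohort",
    "gen_allele_table",
    "gen_splice_training",
    "donor_weight_matrix",
    "acceptor_weight_matrix",
    "uniform_weight_matrix",
]

BASES = "ACGT"

_SENSE_NON_GLY_CODONS = tuple(
    codon
    for codon in (
        a + b + c for a in BASES for b in BASES for c in BASES
    )
    if _translate(codon) not in (None, "Gly")
)


# ---------------------------------------------------------------------------
# architecture and sequence

@dataclass(frozen=True)
class ArchitectureConfig:
    """Geometry of a synthetic collagen IV alpha chain.

    Defaults give a COL4A5-like chain: 23 local collagenous regions
    averaging 20 triplets (so the 46 boundary Gly are ~10% of collagenous
    Gly), short interruptions, a short non-collagenous amino terminus and
    a long NC1 carboxyl terminus, and a 53-exon CDS map.
    """

    n_regions: int = 23
    mean_triplets_per_region: int = 20
    min_triplets_per_region: int = 2
    interruption_length_range: tuple[int, int] = (2, 12)
    amino_terminus_length: int = 27
    carboxyl_terminus_length: int = 229
    n_exons: int = 53

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("need at least one collagenous region")
        if self.min_triplets_per_region < 1:
            raise ValueError("regions must contain at least one triplet")
        if self.mean_triplets_per_region < self.min_triplets_per_region:
            raise ValueError("mean region length below the minimum")


def gen_architecture(
    config: ArchitectureConfig = ArchitectureConfig(), seed: int = 0, chain_id: str = "synthetic_chain"
) -> ChainArchitecture:
    """Random architecture: termini, n_regions collagenous regions, interruptions."""
    rng = np.random.default_rng(seed)
    extra = config.mean_triplets_per_region - config.min_triplets_per_region
    triplet_counts = config.min_triplets_per_region + rng.poisson(
        extra, size=config.n_regions
    )
    interruption_lengths = rng.integers(
        config.interruption_length_range[0],
        config.interruption_length_range[1] + 1,
        size=config.n_regions - 1,
    )
    rows: list[tuple[str, int, int]] = []
    cursor = 1
    rows.append(("amino_terminus", cursor, cursor + config.amino_terminus_length - 1))
    cursor += config.amino_terminus_length
    for i, n_triplets in enumerate(triplet_counts):
        length = 3 * int(n_triplets)
        rows.append(("collagenous", cursor, cursor + length - 1))
        cursor += length
        if i < config.n_regions - 1:
            ilen = int(interruption_lengths[i])
            rows.append(("interruption", cursor, cursor + ilen - 1))
            cursor += ilen
    rows.append(("carboxyl_terminus", cursor, cursor + config.carboxyl_terminus_length - 1))
    total_residues = cursor + config.carboxyl_terminus_length - 1

    # exon map: random cut points over the CDS, each exon at least 12 bases
    cds_length = 3 * total_residues
    n_exons = config.n_exons
    min_exon = 12
    slack = cds_length - min_exon * n_exons
    if slack < 0:
        raise ValueError("CDS too short for the requested exon count")
    cuts = np.sort(rng.choice(slack + 1, size=n_exons - 1, replace=True))
    lengths = np.diff(np.concatenate([[0], cuts, [slack]])) + min_exon
    exon_rows = []
    start = 1
    for index, length in enumerate(lengths, start=1):
        exon_rows.append((index, start, start + int(length) - 1))
        start += int(length)
    return build_architecture(rows, exon_rows, chain_id=chain_id)


def gen_cds(arch: ChainArchitecture, seed: int = 0) -> str:
    """Random CDS realizing the architecture: Gly codons exactly at Gly slots."""
    rng = np.random.default_rng(seed)
    gly_slots = {residue for residue, _, _ in gly_positions(arch)}
    codons = []
    for residue in range(1, arch.length + 1):
        if residue in gly_slots:
            codons.append(GLY_CODONS[rng.integers(len(GLY_CODONS))])
        else:
            codons.append(_SENSE_NON_GLY_CODONS[rng.integers(len(_SENSE_NON_GLY_CODONS))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# variant sampling shared by registry and cohort generators

def _sample_variant(
    rng: np.random.Generator,
    arch: ChainArchitecture,
    cds: str,
    boundary_fraction: float,
):
    """One random collagenous Gly missense variant with its annotation.

    Boundary carriers are drawn with probability ``boundary_fraction``
    (the study's carrier mix, ~15%), then a position uniformly within the
    stratum and a missense single-base change uniformly over the codon's
    missense neighbours.
    """
    positions = gly_positions(arch)
    boundary = [
        p for p, _, _ in positions
        if classify_position(arch, p) is GlyPositionClass.NC_BOUNDARY
    ]
    interior = [
        p for p, _, _ in positions
        if classify_position(arch, p) is not GlyPositionClass.NC_BOUNDARY
    ]
    pick_boundary = rng.random() < boundary_fraction and boundary
    pool = boundary if pick_boundary else interior
    residue = int(pool[rng.integers(len(pool))])
    codon = cds[3 * (residue - 1) : 3 * (residue - 1) + 3]
    neighbours = []
    for offset in range(3):
        for alt in BASES:
            if alt == codon[offset]:
                continue
            mutant = codon[:offset] + alt + codon[offset + 1 :]
            alt_residue = _translate(mutant)
            if alt_residue is not None and alt_residue != "Gly":
                neighbours.append((offset, alt, alt_residue))
    offset, alt, alt_residue = neighbours[rng.integers(len(neighbours))]
    protein = ProteinVariant(residue, "Gly", alt_residue)
    return annotate(arch, protein)


def _feature_row(annotation) -> dict:
    return {
        "variant_label": annotation.variant_label,
        "is_nc_boundary": int(annotation.is_nc_boundary),
        "is_high_destab": int(annotation.is_high_destab),
        "is_carboxyl_block": int(not annotation.is_amino_block),
        "is_amino_end": int(annotation.position_class is GlyPositionClass.AMINO_END),
        "is_carboxyl_end": int(annotation.position_class is GlyPositionClass.CARBOXYL_END),
    }


# ---------------------------------------------------------------------------
# family registry under a proportional-hazards model

@dataclass(frozen=True)
class SurvivalGenConfig:
    """Registry generator: exponential proportional hazards, uniform censoring.

    The family-level observation time is the proportional-hazards draw; a
    family's 1-3 affected male records report ages whose mean equals that
    draw, so the record-level aggregation rules recover it exactly.  The
    reference-stratum median is 26 years (the study-scale age at kidney
    failure); log hazard ratios default to a protective boundary effect
    and a harmful high-destabilisation effect.
    """

    n_families: int = 157
    baseline_median: float = 26.0
    log_hr: dict = field(
        default_factory=lambda: {
            "is_nc_boundary": -0.8,
            "is_high_destab": 0.7,
            "is_carboxyl_block": 0.0,
        }
    )
    censor_uniform: tuple[float, float] = (10.0, 80.0)
    males_per_family: tuple[int, int] = (1, 3)
    boundary_carrier_fraction: float = 0.15
    endpoint: str = "kidney"

    def __post_init__(self) -> None:
        if self.baseline_median <= 0:
            raise ValueError("baseline median must be positive")
        if not 0 <= self.boundary_carrier_fraction <= 1:
            raise ValueError("boundary fraction must be a probability")


_EVENT_TEXT = {
    "kidney": "ESRD, commenced dialysis",
    "hearing": "sensorineural hearing loss diagnosed",
}
_CENSORED_TEXT = {
    "kidney": "renal function preserved at last review",
    "hearing": "normal audiometry and hearing at last review",
}


def gen_registry(
    arch: ChainArchitecture,
    cds: str,
    config: SurvivalGenConfig = SurvivalGenConfig(),
    seed: int = 0,
) -> tuple[list[IndividualRecord], pd.DataFrame]:
    """Simulate a family registry; returns (records, per-family truth table).

    The truth table has one row per family with the variant, its feature
    vector, and the latent time/event before record-level formatting.
    """
    rng = np.random.default_rng(seed)
    baseline_rate = math.log(2.0) / config.baseline_median
    records: list[IndividualRecord] = []
    truth_rows = []
    for i in range(config.n_families):
        family_id = f"F{i + 1:04d}"
        annotation = _sample_variant(rng, arch, cds, config.boundary_carrier_fraction)
        features = _feature_row(annotation)
        linear_predictor = sum(
            config.log_hr.get(name, 0.0) * features[name]
            for name in ("is_nc_boundary", "is_high_destab", "is_carboxyl_block")
        )
        rate = baseline_rate * math.exp(linear_predictor)
        event_time = rng.exponential(1.0 / rate)
        censor_time = rng.uniform(*config.censor_uniform)
        n_males = int(rng.integers(config.males_per_family[0], config.males_per_family[1] + 1))
        event = event_time <= censor_time
        time = event_time if event else censor_time
        truth_rows.append(
            {"family_id": family_id, "time": time, "event": event, **features}
        )
        if event:
            # male ages centred on the family draw so the mean recovers it
            spreads = rng.uniform(0.0, min(2.0, 0.5 * time), size=n_males)
            spreads = spreads - spreads.mean()
            for j, delta in enumerate(spreads):
                records.append(
                    IndividualRecord(
                        family_id=family_id,
                        sex="male",
                        phenotype_text=f"{_EVENT_TEXT[config.endpoint]} at {time + delta:.1f} years",
                        event_age=float(time + delta),
                        variant_ids=(annotation.variant_label,),
                    )
                )
        else:
            for j in range(n_males):
                records.append(
                    IndividualRecord(
                        family_id=family_id,
                        sex="male",
                        phenotype_text=f"{_CENSORED_TEXT[config.endpoint]}, aged {time:.1f}",
                        last_seen_age=float(time),
                        variant_ids=(annotation.variant_label,),
                    )
                )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# case-control cohort under a logistic model

@dataclass(frozen=True)
class LogisticGenConfig:
    """Case-control generator with the haematuria-model coefficients."""

    n_individuals: int = 304
    coefficients: dict = field(
        default_factory=lambda: {
            "intercept": -2.41,
            "is_nc_boundary": -1.25,
            "is_high_destab": 0.94,
            "is_carboxyl_block": 0.24,
        }
    )
    boundary_carrier_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")


def gen_cohort(
    arch: ChainArchitecture,
    cds: str,
    config: LogisticGenConfig = LogisticGenConfig(),
    seed: int = 0,
    gene_labels: tuple[str, str] = ("COL4A3", "COL4A4"),
) -> pd.DataFrame:
    """Simulate unrelated heterozygous carriers with a Bernoulli outcome."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(config.n_individuals):
        annotation = _sample_variant(rng, arch, cds, config.boundary_carrier_fraction)
        features = _feature_row(annotation)
        eta = config.coefficients.get("intercept", 0.0) + sum(
            config.coefficients.get(name, 0.0) * features[name]
            for name in ("is_nc_boundary", "is_high_destab", "is_carboxyl_block")
        )
        probability = 1.0 / (1.0 + math.exp(-eta))
        rows.append(
            {
                "individual_id": f"I{i + 1:05d}",
                "gene": gene_labels[int(rng.integers(len(gene_labels)))],
                "outcome": int(rng.random() < probability),
                **features,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population allele table under the mutation-rate model

@dataclass(frozen=True)
class AlleleGenConfig:
    """Allele-table generator: draws proportional to mutational opportunity."""

    n_draws: int = 500
    male_total: int = 70_000
    female_total: int = 70_000

    def __post_init__(self) -> None:
        if self.n_draws < 1 or self.male_total < 1 or self.female_total < 1:
            raise ValueError("draws and population totals must be positive")


def gen_allele_table(
    arch: ChainArchitecture,
    cds: str,
    rate_table: RateTable,
    config: AlleleGenConfig = AlleleGenConfig(),
    seed: int = 0,
) -> tuple[list[AlleleRecord], dict]:
    """Sample allele observations over the chain's Gly missense SNV space.

    Each draw picks a site proportional to its context rate and lands in a
    hemizygous male or a heterozygous female X with probability given by
    the X-chromosome share of each sex.  Returns the per-variant records
    and a summary with the boundary share of the draws.
    """
    rng = np.random.default_rng(seed)
    sites = enumerate_gly_missense(arch, cds, rate_table)
    weights = np.array([site.rate for site in sites])
    weights = weights / weights.sum()
    draws = rng.choice(len(sites), size=config.n_draws, p=weights)
    male_allele_share = config.male_total / (config.male_total + 2 * config.female_total)
    is_male = rng.random(config.n_draws) < male_allele_share

    hem: dict[int, int] = {}
    het: dict[int, int] = {}
    for site_index, male in zip(draws, is_male):
        bucket = hem if male else het
        bucket[site_index] = bucket.get(site_index, 0) + 1
    records = []
    boundary_draws = 0
    for site_index in sorted(set(hem) | set(het)):
        site = sites[site_index]
        label = f"Gly{site.residue_index}{site.alt_residue}"
        records.append(
            AlleleRecord(
                variant_label=label,
                hemizygote_count=hem.get(site_index, 0),
                heterozygote_count=het.get(site_index, 0),
                homozygote_count=0,
            )
        )
    boundary_draws = int(sum(1 for d in draws if sites[d].is_boundary))
    summary = {
        "n_draws": config.n_draws,
        "boundary_draws": boundary_draws,
        "boundary_draw_fraction": boundary_draws / config.n_draws,
        "n_unique_variants": len(records),
        "n_unique_boundary_variants": sum(
            1 for d in set(draws) if sites[d].is_boundary
        ),
    }
    return records, summary


# ---------------------------------------------------------------------------
# splice-site training windows

def donor_weight_matrix() -> np.ndarray:
    """Per-position base weights of a canonical 9-mer donor site (cAG|GTaagt)."""
    weak, strong = 0.05, 0.85
    consensus = "CAGGTAAGT"
    matrix = np.full((9, 4), (1.0 - strong) / 3)
    for i, base in enumerate(consensus):
        matrix[i, BASES.index(base)] = strong
    # the three exonic positions are less constrained than the GT core
    matrix[:3] = 0.55 * matrix[:3] + 0.45 * 0.25
    matrix[5:] = 0.7 * matrix[5:] + 0.3 * 0.25
    del weak
    return matrix / matrix.sum(axis=1, keepdims=True)


def acceptor_weight_matrix() -> np.ndarray:
    """Per-position base weights of a 23-mer acceptor: polypyrimidine tract + AG | 3 exonic."""
    matrix = np.full((23, 4), 0.25)
    for i in range(18):  # pyrimidine-rich tract
        matrix[i] = [0.10, 0.40, 0.10, 0.40]
    matrix[18] = [0.25, 0.30, 0.15, 0.30]
    matrix[19] = [0.95, 0.02, 0.01, 0.02]  # invariant A
    matrix[20] = [0.01, 0.02, 0.95, 0.02]  # invariant G
    return matrix / matrix.sum(axis=1, keepdims=True)


def uniform_weight_matrix(length: int) -> np.ndarray:
    return np.full((length, 4), 0.25)


@dataclass(frozen=True)
class SpliceGenConfig:
    site_kind: str = "donor_5prime"
    n_windows: int = 500
    weight_matrix: np.ndarray | None = None  # default canonical matrix per kind


def gen_splice_training(
    config: SpliceGenConfig = SpliceGenConfig(), seed: int = 0
) -> tuple[list[str], np.ndarray]:
    """Draw aligned true-site windows from a per-position weight matrix.

    Returns (windows, generating matrix) so the trainer can be validated
    against the ground-truth distribution.
    """
    if config.weight_matrix is not None:
        matrix = np.asarray(config.weight_matrix, dtype=float)
    elif config.site_kind == "donor_5prime":
        matrix = donor_weight_matrix()
    elif config.site_kind == "acceptor_3prime":
        matrix = acceptor_weight_matrix()
    else:
        raise ValueError(f"unknown site kind {config.site_kind!r}")
    rng = np.random.default_rng(seed)
    length = matrix.shape[0]
    windows = []
    for _ in range(config.n_windows):
        indices = [rng.choice(4, p=matrix[i]) for i in range(length)]
        windows.append("".join(BASES[j] for j in indices))
    return windows, matrix
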