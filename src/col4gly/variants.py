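"""Variant notation parsing and the per-variant molecular feature vector.

Three molecular features drive the downstream genotype-phenotype stages for
each Gly missense variant: molecular location (exons 1-20 vs 21 to the
carboxyl terminus), adjacency to a non-collagenous region (the "boundary"
feature), and the destabilising potential of the replacing residue.  Gly is
the only residue small enough for the core of the triple helix, and the
eight residues reachable from a Gly codon by a single nucleotide change
fall into mildly (Ala, Ser, Cys) and highly (Arg, Val, Glu, Asp, Trp)
destabilising classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

from .chain_model import ChainArchitecture, GlyPositionClass, boundary_side, classify_position, exon_location

__all__ = [
    "CdnaVariant",
    "ProteinVariant",
    "VariantAnnotation",
    "VariantParseError",
    "ConsistencyError",
    "ClassificationError",
    "parse_cdna",
    "parse_protein",
    "codon_of",
    "reachable_substitutions",
    "destabilisation_class",
    "annotate",
    "MILD_RESIDUES",
    "HIGH_RESIDUES",
    "GLY_CODONS",
]

BASES = "ACGT"
GLY_CODONS = ("GGA", "GGC", "GGG", "GGT")
MILD_RESIDUES = frozenset({"Ala", "Ser", "Cys"})
HIGH_RESIDUES = frozenset({"Arg", "Val", "Glu", "Asp", "Trp"})

_AA3 = {seq3(a).capitalize() for a in "ACDEFGHIKLMNPQRSTVWY"}
_AA1_TO_3 = {a: seq3(a).capitalize() for a in "ACDEFGHIKLMNPQRSTVWY"}


class VariantParseError(ValueError):
    """Malformed or out-of-scope variant notation."""


class ConsistencyError(ValueError):
    """cDNA and protein descriptions of a variant disagree."""


class ClassificationError(ValueError):
    """Variant cannot be placed on the chain as a collagenous Gly."""


@dataclass(frozen=True)
class CdnaVariant:
    """Single-nucleotide CDS change, e.g. c.2858G>T."""

    cdna_position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise VariantParseError(f"bases must be one of {BASES}: {self}")
        if self.ref_base == self.alt_base:
            raise VariantParseError(f"ref equals alt in {self}")
        if self.cdna_position < 1:
            raise VariantParseError(f"non-positive cDNA position in {self}")

    def __str__(self) -> str:
        return f"{self.cdna_position}{self.ref_base}>{self.alt_base}"


@dataclass(frozen=True)
class ProteinVariant:
    """Missense change in protein coordinates, e.g. Gly953Val."""

    residue_index: int
    ref_residue: str
    alt_residue: str

    def __post_init__(self) -> None:
        for res in (self.ref_residue, self.alt_residue):
            if res not in _AA3:
                raise VariantParseError(f"unknown residue code {res!r}")
        if self.ref_residue == self.alt_residue:
            raise VariantParseError(f"ref equals alt in {self}")
        if self.residue_index < 1:
            raise VariantParseError(f"non-positive residue index in {self}")

    def __str__(self) -> str:
        return f"{self.ref_residue}{self.residue_index}{self.alt_residue}"


_CDNA_RE = re.compile(r"^(?:c\.)?(\d+)([ACGT])>([ACGT])$", re.IGNORECASE)
_PROT3_RE = re.compile(r"^(?:p\.)?([A-Za-z]{3})(\d+)([A-Za-z]{3})$")
_PROT1_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")


def parse_cdna(text: str) -> CdnaVariant:
    """Parse an HGVS-like cDNA SNV such as ``2858G>T`` or ``c.1871G>A``.

    Only simple substitutions in CDS coordinates are in scope; deletions,
    insertions, duplications and intronic offsets are rejected.
    """
    cleaned = text.strip()
    if not cleaned:
        raise VariantParseError("empty cDNA string")
    match = _CDNA_RE.match(cleaned)
    if match is None:
        lowered = cleaned.lower()
        if any(tag in lowered for tag in ("del", "ins", "dup")):
            raise VariantParseError(f"not a single-nucleotide substitution: {text!r}")
        if re.search(r"\d[+-]\d", cleaned):
            raise VariantParseError(f"intronic offset not supported: {text!r}")
        raise VariantParseError(f"cannot parse cDNA variant {text!r}")
    pos, ref, alt = match.groups()
    return CdnaVariant(int(pos), ref.upper(), alt.upper())


def parse_protein(text: str) -> ProteinVariant:
    """Parse ``Gly953Val``, ``p.Gly953Val`` or one-letter ``G953V`` forms."""
    cleaned = text.strip()
    if not cleaned:
        raise VariantParseError("empty protein string")
    match = _PROT3_RE.match(cleaned)
    if match is not None:
        ref, pos, alt = match.groups()
        ref, alt = ref.capitalize(), alt.capitalize()
        if ref not in _AA3 or alt not in _AA3:
            raise VariantParseError(f"unknown residue code in {text!r}")
        return ProteinVariant(int(pos), ref, alt)
    match = _PROT1_RE.match(cleaned)
    if match is not None:
        ref1, pos, alt1 = match.groups()
        if ref1 not in _AA1_TO_3 or alt1 not in _AA1_TO_3:
            raise VariantParseError(f"unknown residue code in {text!r}")
        return ProteinVariant(int(pos), _AA1_TO_3[ref1], _AA1_TO_3[alt1])
    raise VariantParseError(f"cannot parse protein variant {text!r}")


def codon_of(cdna_position: int) -> tuple[int, int]:
    """Residue index and within-codon offset (1..3) of a CDS nucleotide."""
    if cdna_position < 1:
        raise ValueError("cDNA position must be positive")
    residue_index = (cdna_position + 2) // 3
    offset = cdna_position - 3 * (residue_index - 1)
    return residue_index, offset


def _translate(codon: str) -> str | None:
    """Three-letter residue, or None for a stop codon."""
    if codon in standard_dna_table.stop_codons:
        return None
    return seq3(standard_dna_table.forward_table[codon]).capitalize()


def reachable_substitutions(gly_codon: str) -> set[str]:
    """Missense residues reachable from a Gly codon by one base change.

    Synonymous (Gly) and nonsense (stop) outcomes are excluded.  The union
    over the four Gly codons is exactly the eight residues of the two
    destabilisation classes.
    """
    codon = gly_codon.upper()
    if codon not in GLY_CODONS:
        raise ValueError(f"{gly_codon!r} does not encode Gly")
    out: set[str] = set()
    for offset in range(3):
        for base in BASES:
            if base == codon[offset]:
                continue
            mutant = codon[:offset] + base + codon[offset + 1 :]
            residue = _translate(mutant)
            if residue is not None and residue != "Gly":
                out.add(residue)
    return out


def destabilisation_class(alt_residue: str) -> str:
    """``mild`` for Ala/Ser/Cys, ``high`` for Arg/Val/Glu/Asp/Trp."""
    residue = alt_residue.capitalize()
    if residue in MILD_RESIDUES:
        return "mild"
    if residue in HIGH_RESIDUES:
        return "high"
    raise ValueError(
        f"{alt_residue!r} is not reachable from a Gly codon by one substitution"
    )


@dataclass(frozen=True)
class VariantAnnotation:
    """One Gly missense variant with its derived molecular features."""

    gene: str
    protein: ProteinVariant
    cdna: CdnaVariant | None
    position_class: GlyPositionClass
    boundary_side: str | None  # amino | carboxyl, boundary Gly only
    exon_index: int
    is_amino_block: bool  # exons 1-20
    destab_class: str  # mild | high
    local_region_ordinal: int
    splice_flagged: bool = False

    @property
    def is_nc_boundary(self) -> bool:
        return self.position_class is GlyPositionClass.NC_BOUNDARY

    @property
    def is_high_destab(self) -> bool:
        return self.destab_class == "high"

    @property
    def variant_label(self) -> str:
        return str(self.protein)


def annotate(
    arch: ChainArchitecture,
    protein: ProteinVariant,
    cdna: CdnaVariant | None = None,
    splice_flagged: bool = False,
) -> VariantAnnotation:
    """Derive the full molecular feature vector for one Gly missense variant.

    Requires the reference residue to be a collagenous Gly of ``arch``.
    When a cDNA description is given it must map to the same codon as the
    protein description; the exon is taken from the substituted base, or
    from the first base of the codon when only the protein form is known.
    """
    if protein.ref_residue != "Gly":
        raise ClassificationError(f"{protein} does not substitute a Gly residue")
    if cdna is not None:
        residue_index, _ = codon_of(cdna.cdna_position)
        if residue_index != protein.residue_index:
            raise ConsistencyError(
                f"cDNA {cdna} maps to residue {residue_index}, "
                f"protein description says {protein.residue_index}"
            )
    position_class = classify_position(arch, protein.residue_index)
    if position_class in (
        GlyPositionClass.NON_COLLAGENOUS,
        GlyPositionClass.COLLAGENOUS_NON_GLY,
    ):
        raise ClassificationError(
            f"residue {protein.residue_index} of {arch.chain_id} is not a "
            f"collagenous Gly position ({position_class.value})"
        )
    side = (
        boundary_side(arch, protein.residue_index)
        if position_class is GlyPositionClass.NC_BOUNDARY
        else None
    )
    exon_base = (
        cdna.cdna_position if cdna is not None else 3 * (protein.residue_index - 1) + 1
    )
    exon_index, is_amino_block = exon_location(arch, exon_base)
    region_ordinal = next(
        region
        for residue, region, _ in _gly_lookup(arch)
        if residue == protein.residue_index
    )
    return VariantAnnotation(
        gene=arch.chain_id,
        protein=protein,
        cdna=cdna,
        position_class=position_class,
        boundary_side=side,
        exon_index=exon_index,
        is_amino_block=is_amino_block,
        destab_class=destabilisation_class(protein.alt_residue),
        local_region_ordinal=region_ordinal,
        splice_flagged=splice_flagged,
    )


def _gly_lookup(arch: ChainArchitecture):
    from .chain_model import gly_positions

    return gly_positions(arch)
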