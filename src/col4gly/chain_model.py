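"""Collagen IV alpha-chain domain architecture.

A collagen IV alpha chain is modelled as an ordered tiling of segments:
a non-collagenous amino terminus, alternating collagenous Gly-Xaa-Yaa
regions and short non-collagenous interruptions, and a non-collagenous
carboxyl (NC1) terminus.  Every collagenous segment is a whole number of
triplets whose first residue is the obligate Gly.

Each uninterrupted collagenous stretch is a "local collagenous region"
with its own amino and carboxyl ends; the first and last Gly of each
region sit against a non-collagenous interruption or terminus and are the
"non-collagenous boundary" Gly residues, the mild-phenotype stratum of
the analysis this package implements.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SegmentKind",
    "ChainSegment",
    "ExonSpan",
    "ChainArchitecture",
    "GlyPositionClass",
    "ArchitectureError",
    "build_architecture",
    "gly_positions",
    "classify_position",
    "boundary_side",
    "exon_location",
    "read_architecture",
    "write_architecture",
]

AMINO_EXON_LIMIT = 20  # exons 1..20 form the amino block of the molecular-location feature


class ArchitectureError(ValueError):
    """Structural problem in a chain architecture definition."""


class SegmentKind(str, enum.Enum):
    AMINO_TERMINUS = "amino_terminus"
    COLLAGENOUS = "collagenous"
    INTERRUPTION = "interruption"
    CARBOXYL_TERMINUS = "carboxyl_terminus"


NON_COLLAGENOUS_KINDS = frozenset(
    {SegmentKind.AMINO_TERMINUS, SegmentKind.INTERRUPTION, SegmentKind.CARBOXYL_TERMINUS}
)


class GlyPositionClass(str, enum.Enum):
    """Partition of residue positions by collagenous context.

    ``nc_boundary``       first or last Gly of a local collagenous region
    ``amino_end``         Gly ordinals 2-3 of a region (boundary excluded)
    ``carboxyl_end``      the two Gly immediately before the last
    ``central``           any other collagenous Gly
    ``non_collagenous``   residue inside a terminus or interruption
    ``collagenous_non_gly``  Xaa/Yaa position of a triplet
    """

    NC_BOUNDARY = "nc_boundary"
    AMINO_END = "amino_end"
    CARBOXYL_END = "carboxyl_end"
    CENTRAL = "central"
    NON_COLLAGENOUS = "non_collagenous"
    COLLAGENOUS_NON_GLY = "collagenous_non_gly"


@dataclass(frozen=True)
class ChainSegment:
    kind: SegmentKind
    start_residue: int
    end_residue: int

    def __post_init__(self) -> None:
        if self.start_residue < 1 or self.end_residue < self.start_residue:
            raise ArchitectureError(
                f"bad segment bounds [{self.start_residue}, {self.end_residue}]"
            )
        if self.kind is SegmentKind.COLLAGENOUS and self.length % 3 != 0:
            raise ArchitectureError(
                f"collagenous segment [{self.start_residue}-{self.end_residue}] has "
                f"length {self.length}, not a whole number of Gly-Xaa-Yaa triplets"
            )

    @property
    def length(self) -> int:
        return self.end_residue - self.start_residue + 1

    @property
    def n_triplets(self) -> int:
        if self.kind is not SegmentKind.COLLAGENOUS:
            return 0
        return self.length // 3


@dataclass(frozen=True)
class ExonSpan:
    index: int
    cdna_start: int  # 1-based inclusive, position 1 = A of the initiator ATG
    cdna_end: int


@dataclass(frozen=True)
class ChainArchitecture:
    """Validated segment tiling plus exon map for one alpha chain."""

    chain_id: str
    segments: tuple[ChainSegment, ...]
    exon_map: tuple[ExonSpan, ...] = ()
    _class_by_residue: tuple[GlyPositionClass, ...] = field(
        default=(), repr=False, compare=False
    )

    @property
    def length(self) -> int:
        return self.segments[-1].end_residue

    @property
    def n_exons(self) -> int:
        return len(self.exon_map)

    @property
    def collagenous_regions(self) -> tuple[ChainSegment, ...]:
        return tuple(s for s in self.segments if s.kind is SegmentKind.COLLAGENOUS)


def _validate_segments(segments: Sequence[ChainSegment]) -> None:
    if not segments:
        raise ArchitectureError("no segments given")
    if segments[0].kind is not SegmentKind.AMINO_TERMINUS:
        raise ArchitectureError("first segment must be the amino terminus")
    if segments[-1].kind is not SegmentKind.CARBOXYL_TERMINUS:
        raise ArchitectureError("last segment must be the carboxyl terminus")
    n_amino = sum(1 for s in segments if s.kind is SegmentKind.AMINO_TERMINUS)
    n_carboxyl = sum(1 for s in segments if s.kind is SegmentKind.CARBOXYL_TERMINUS)
    if n_amino != 1 or n_carboxyl != 1:
        raise ArchitectureError("exactly one amino and one carboxyl terminus required")
    if segments[0].start_residue != 1:
        raise ArchitectureError("amino terminus must start at residue 1")
    for prev, cur in zip(segments, segments[1:]):
        if cur.start_residue != prev.end_residue + 1:
            if cur.start_residue > prev.end_residue + 1:
                raise ArchitectureError(
                    f"gap between residues {prev.end_residue} and {cur.start_residue}"
                )
            raise ArchitectureError(
                f"overlap: segment starting at {cur.start_residue} overlaps "
                f"segment ending at {prev.end_residue}"
            )


def _validate_exon_map(exon_map: Sequence[ExonSpan]) -> None:
    for span in exon_map:
        if span.cdna_start < 1 or span.cdna_end < span.cdna_start:
            raise ArchitectureError(f"bad exon span {span}")
    if exon_map and exon_map[0].cdna_start != 1:
        raise ArchitectureError("exon map must start at cDNA position 1")
    for prev, cur in zip(exon_map, exon_map[1:]):
        if cur.cdna_start != prev.cdna_end + 1:
            raise ArchitectureError(
                f"exon map not contiguous between cDNA {prev.cdna_end} and {cur.cdna_start}"
            )


def _region_gly_classes(n_gly: int) -> list[GlyPositionClass]:
    """Class of each Gly ordinal (1..n_gly) within one local collagenous region.

    Precedence when ordinal ranges overlap in short regions:
    nc_boundary > carboxyl_end > amino_end > central.  Trimerisation runs
    carboxyl-to-amino, so the carboxyl-end label wins over amino-end, and
    boundary status is the primary stratifier.  Regions with only 1-2 Gly
    are all boundary.
    """
    classes = [GlyPositionClass.CENTRAL] * n_gly
    for ordinal in (2, 3):  # the 2 Gly at the amino end, not counting the boundary Gly
        if ordinal <= n_gly:
            classes[ordinal - 1] = GlyPositionClass.AMINO_END
    for ordinal in (n_gly - 2, n_gly - 1):  # the 2 Gly just before the last
        if ordinal >= 1:
            classes[ordinal - 1] = GlyPositionClass.CARBOXYL_END
    classes[0] = GlyPositionClass.NC_BOUNDARY
    classes[n_gly - 1] = GlyPositionClass.NC_BOUNDARY
    return classes


def build_architecture(
    segment_table: Iterable[tuple[str, int, int]],
    exon_table: Iterable[tuple[int, int, int]] = (),
    chain_id: str = "chain",
) -> ChainArchitecture:
    """Build and validate a :class:`ChainArchitecture` from plain tables.

    Parameters
    ----------
    segment_table
        Rows of ``(kind, start_residue, end_residue)``, amino-to-carboxyl
        order, 1-based inclusive protein coordinates.
    exon_table
        Rows of ``(exon_index, cdna_start, cdna_end)``, 1-based inclusive
        CDS coordinates (position 1 = A of ATG).  May be empty for purely
        protein-level work.
    """
    segments = tuple(
        ChainSegment(SegmentKind(kind), int(start), int(end))
        for kind, start, end in segment_table
    )
    _validate_segments(segments)
    exon_map = tuple(
        ExonSpan(int(i), int(s), int(e)) for i, s, e in exon_table
    )
    _validate_exon_map(exon_map)

    classes: list[GlyPositionClass] = []
    for seg in segments:
        if seg.kind in NON_COLLAGENOUS_KINDS:
            classes.extend([GlyPositionClass.NON_COLLAGENOUS] * seg.length)
        else:
            per_gly = _region_gly_classes(seg.n_triplets)
            for gly_class in per_gly:
                classes.append(gly_class)
                classes.extend([GlyPositionClass.COLLAGENOUS_NON_GLY] * 2)
    return ChainArchitecture(chain_id, segments, exon_map, tuple(classes))


def gly_positions(arch: ChainArchitecture) -> list[tuple[int, int, int]]:
    """All Gly slots: ``(residue_index, region_ordinal, gly_ordinal_in_region)``.

    Lists the first residue of every triplet of every collagenous segment in
    amino-to-carboxyl order.  Region ordinals count local collagenous
    regions from 1 at the amino end.
    """
    out: list[tuple[int, int, int]] = []
    for region_ordinal, seg in enumerate(arch.collagenous_regions, start=1):
        for gly_ordinal in range(1, seg.n_triplets + 1):
            residue = seg.start_residue + 3 * (gly_ordinal - 1)
            out.append((residue, region_ordinal, gly_ordinal))
    return out


def classify_position(arch: ChainArchitecture, residue_index: int) -> GlyPositionClass:
    """Class of one residue position; classes partition positions 1..L."""
    if not 1 <= residue_index <= arch.length:
        raise IndexError(
            f"residue {residue_index} outside chain {arch.chain_id} (1..{arch.length})"
        )
    return arch._class_by_residue[residue_index - 1]


def boundary_side(arch: ChainArchitecture, residue_index: int) -> str:
    """Which side of its adjacent non-collagenous region a boundary Gly sits on.

    The last Gly of a region lies on the *amino* side of the following
    interruption/terminus; the first Gly lies on the *carboxyl* side of the
    preceding one.  A single-Gly region is adjacent to both; it is reported
    as ``amino`` (the side the downstream analyses stratify on).
    """
    if classify_position(arch, residue_index) is not GlyPositionClass.NC_BOUNDARY:
        raise ValueError(f"residue {residue_index} is not a non-collagenous boundary Gly")
    for seg in arch.collagenous_regions:
        if seg.start_residue <= residue_index <= seg.end_residue:
            last_gly = seg.start_residue + 3 * (seg.n_triplets - 1)
            return "amino" if residue_index == last_gly else "carboxyl"
    raise AssertionError("unreachable: boundary Gly outside all collagenous segments")


def exon_location(arch: ChainArchitecture, cdna_position: int) -> tuple[int, bool]:
    """Exon containing a CDS nucleotide and the exons-1-to-20 amino-block flag."""
    if not arch.exon_map:
        raise ArchitectureError(f"chain {arch.chain_id} has no exon map")
    cds_end = arch.exon_map[-1].cdna_end
    if not 1 <= cdna_position <= cds_end:
        raise IndexError(f"cDNA position {cdna_position} outside CDS (1..{cds_end})")
    for span in arch.exon_map:
        if span.cdna_start <= cdna_position <= span.cdna_end:
            return span.index, span.index <= AMINO_EXON_LIMIT
    raise AssertionError("unreachable: contiguous exon map")


# ---------------------------------------------------------------------------
# file interface: tab-separated, '#' comments

def read_architecture(
    segment_path: str | Path,
    exon_path: str | Path | None = None,
    chain_id: str | None = None,
) -> ChainArchitecture:
    """Read an architecture from segment and exon tables.

    Segment file columns: ``kind  start  end``; exon file columns:
    ``exon  cdna_start  cdna_end``.  Lines starting with '#' are comments.
    """
    segment_path = Path(segment_path)
    seg_rows = []
    for line in segment_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, start, end = line.split("\t")[:3]
        seg_rows.append((kind, int(start), int(end)))
    exon_rows = []
    if exon_path is not None:
        for line in Path(exon_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx, start, end = line.split("\t")[:3]
            exon_rows.append((int(idx), int(start), int(end)))
    return build_architecture(
        seg_rows, exon_rows, chain_id=chain_id or segment_path.stem
    )


def write_architecture(
    arch: ChainArchitecture,
    segment_path: str | Path,
    exon_path: str | Path | None = None,
    header_comment: str | None = None,
) -> None:
    lines = []
    if header_comment:
        lines.extend(f"# {text}" for text in header_comment.splitlines())
    lines.append("#kind\tstart\tend")
    for seg in arch.segments:
        lines.append(f"{seg.kind.value}\t{seg.start_residue}\t{seg.end_residue}")
    Path(segment_path).write_text("\n".join(lines) + "\n")
    if exon_path is not None and arch.exon_map:
        elines = ["#exon\tcdna_start\tcdna_end"]
        for span in arch.exon_map:
            elines.append(f"{span.index}\t{span.cdna_start}\t{span.cdna_end}")
        Path(exon_path).write_text("\n".join(elines) + "\n")
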