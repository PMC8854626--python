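"""Chain architecture: construction, Gly enumeration, position classes."""

import numpy as np
import pytest

from col4gly.chain_model import (
    ArchitectureError,
    GlyPositionClass,
    build_architecture,
    boundary_side,
    classify_position,
    exon_location,
    gly_positions,
    read_architecture,
    write_architecture,
)


def test_toy_architecture_is_valid(toy_arch):
    assert toy_arch.length == 50
    assert toy_arch.n_exons == 2
    assert len(toy_arch.collagenous_regions) == 1


@pytest.mark.parametrize(
    "segments, message",
    [
        ([("amino_terminus", 1, 10), ("collagenous", 12, 41), ("carboxyl_terminus", 42, 50)], "gap"),
        ([("amino_terminus", 1, 10), ("collagenous", 9, 38), ("carboxyl_terminus", 39, 50)], "overlap"),
        ([("amino_terminus", 1, 10), ("collagenous", 11, 39), ("carboxyl_terminus", 40, 50)], "triplet"),
    ],
)
def test_structural_errors(segments, message):
    with pytest.raises(ArchitectureError, match=message):
        build_architecture(segments)


def test_gly_positions_single_region(toy_arch):
    positions = gly_positions(toy_arch)
    assert [p for p, _, _ in positions] == [11, 14, 17, 20, 23, 26, 29, 32, 35, 38]
    assert all(region == 1 for _, region, _ in positions)
    assert [ordinal for _, _, ordinal in positions] == list(range(1, 11))


def test_gly_positions_two_regions(two_region_arch):
    positions = gly_positions(two_region_arch)
    assert len(positions) == 12
    assert sorted({region for _, region, _ in positions}) == [1, 2]


def test_gly_positions_no_collagenous_region():
    arch = build_architecture(
        [("amino_terminus", 1, 5), ("carboxyl_terminus", 6, 10)]
    )
    assert gly_positions(arch) == []


@pytest.mark.parametrize(
    "residue, expected",
    [
        (11, GlyPositionClass.NC_BOUNDARY),
        (38, GlyPositionClass.NC_BOUNDARY),
        (14, GlyPositionClass.AMINO_END),
        (17, GlyPositionClass.AMINO_END),
        (32, GlyPositionClass.CARBOXYL_END),
        (35, GlyPositionClass.CARBOXYL_END),
        (23, GlyPositionClass.CENTRAL),
        (12, GlyPositionClass.COLLAGENOUS_NON_GLY),
        (5, GlyPositionClass.NON_COLLAGENOUS),
    ],
)
def test_classify_position_toy(toy_arch, residue, expected):
    assert classify_position(toy_arch, residue) is expected


def test_classify_out_of_range(toy_arch):
    with pytest.raises(IndexError):
        classify_position(toy_arch, 0)
    with pytest.raises(IndexError):
        classify_position(toy_arch, 51)


def test_boundary_side(toy_arch):
    # first Gly of a region is on the carboxyl side of the preceding NC region,
    # last Gly on the amino side of the following one
    assert boundary_side(toy_arch, 11) == "carboxyl"
    assert boundary_side(toy_arch, 38) == "amino"
    with pytest.raises(ValueError):
        boundary_side(toy_arch, 23)


def test_exon_location(toy_arch):
    assert exon_location(toy_arch, 90) == (1, True)
    assert exon_location(toy_arch, 91) == (2, True)
    with pytest.raises(IndexError):
        exon_location(toy_arch, 151)


def test_exon_amino_block_threshold():
    # 21 tiny exons: a variant in exon 21 is outside the amino block
    exons = [(i, 3 * (i - 1) + 1, 3 * i) for i in range(1, 22)]
    arch = build_architecture(
        [("amino_terminus", 1, 9), ("collagenous", 10, 15), ("carboxyl_terminus", 16, 21)],
        exons,
    )
    assert exon_location(arch, 60) == (20, True)
    assert exon_location(arch, 61) == (21, False)


# ---------------------------------------------------------------------------
# invariants

def _random_architecture(rng):
    rows = []
    cursor = 1
    nc_len = int(rng.integers(1, 8))
    rows.append(("amino_terminus", cursor, cursor + nc_len - 1))
    cursor += nc_len
    n_regions = int(rng.integers(1, 11))
    for i in range(n_regions):
        triplets = int(rng.integers(1, 9))
        rows.append(("collagenous", cursor, cursor + 3 * triplets - 1))
        cursor += 3 * triplets
        if i < n_regions - 1:
            ilen = int(rng.integers(1, 6))
            rows.append(("interruption", cursor, cursor + ilen - 1))
            cursor += ilen
    nc_len = int(rng.integers(1, 8))
    rows.append(("carboxyl_terminus", cursor, cursor + nc_len - 1))
    return build_architecture(rows)


def _brute_force_classes(arch):
    """Independent enumeration straight from the definitions.

    Boundary = first/last Gly of each region; amino end = 2nd and 3rd Gly;
    carboxyl end = 2nd- and 3rd-from-last Gly; precedence boundary >
    carboxyl > amino > central; everything else non-collagenous or
    Xaa/Yaa.
    """
    out = {}
    for residue in range(1, arch.length + 1):
        out[residue] = GlyPositionClass.NON_COLLAGENOUS
    for seg in arch.collagenous_regions:
        gly = list(range(seg.start_residue, seg.end_residue + 1, 3))
        for residue in range(seg.start_residue, seg.end_residue + 1):
            out[residue] = GlyPositionClass.COLLAGENOUS_NON_GLY
        for i, residue in enumerate(gly):
            ordinal = i + 1
            from_end = len(gly) - i
            if ordinal == 1 or from_end == 1:
                out[residue] = GlyPositionClass.NC_BOUNDARY
            elif from_end in (2, 3):
                out[residue] = GlyPositionClass.CARBOXYL_END
            elif ordinal in (2, 3):
                out[residue] = GlyPositionClass.AMINO_END
            else:
                out[residue] = GlyPositionClass.CENTRAL
    return out


def test_classification_matches_brute_force_enumeration():
    rng = np.random.default_rng(42)
    for _ in range(50):
        arch = _random_architecture(rng)
        expected = _brute_force_classes(arch)
        for residue in range(1, arch.length + 1):
            assert classify_position(arch, residue) is expected[residue], (
                arch.segments,
                residue,
            )


def test_class_partition_and_boundary_count():
    rng = np.random.default_rng(7)
    for _ in range(30):
        arch = _random_architecture(rng)
        counts = {}
        for residue in range(1, arch.length + 1):
            cls = classify_position(arch, residue)
            counts[cls] = counts.get(cls, 0) + 1
        assert sum(counts.values()) == arch.length
        regions = arch.collagenous_regions
        expected_boundary = sum(2 if s.n_triplets >= 2 else 1 for s in regions)
        assert counts.get(GlyPositionClass.NC_BOUNDARY, 0) == expected_boundary
        # every enumerated Gly slot carries a Gly class
        gly_classes = {
            classify_position(arch, residue) for residue, _, _ in gly_positions(arch)
        }
        assert gly_classes <= {
            GlyPositionClass.NC_BOUNDARY,
            GlyPositionClass.AMINO_END,
            GlyPositionClass.CARBOXYL_END,
            GlyPositionClass.CENTRAL,
        }


def test_architecture_file_round_trip(tmp_path, two_region_arch):
    seg = tmp_path / "segments.tsv"
    exo = tmp_path / "exons.tsv"
    write_architecture(two_region_arch, seg, exo, header_comment="round trip")
    again = read_architecture(seg, exo, chain_id="two_region")
    assert again.segments == two_region_arch.segments
    assert again.exon_map == two_region_arch.exon_map
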