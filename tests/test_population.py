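"""Substitution-rate expectation, exact binomial test, allele arithmetic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import binom

from col4gly.chain_model import build_architecture, classify_position, GlyPositionClass, gly_positions
from col4gly.population import (
    AlleleRecord,
    RateTable,
    allele_total,
    carrier_prevalence,
    context_rate,
    default_rate_table,
    enumerate_gly_missense,
    exact_binomial,
    expected_boundary_fraction,
    read_allele_table,
    read_rate_table,
    symmetrize,
    write_rate_table,
)

_CODE = {  # reduced code oracle: Gly codons and stops only
    "stops": {"TAA", "TAG", "TGA"},
    "gly": {"GGA", "GGC", "GGG", "GGT"},
}


def _toy_gly_arch(n_triplets=10):
    return build_architecture(
        [
            ("amino_terminus", 1, 3),
            ("collagenous", 4, 3 + 3 * n_triplets),
            ("carboxyl_terminus", 4 + 3 * n_triplets, 6 + 3 * n_triplets),
        ]
    )


def _cds_all_ggt(arch):
    gly = {r for r, _, _ in gly_positions(arch)}
    return "".join("GGT" if r in gly else "CCT" for r in range(1, arch.length + 1))


# ---------------------------------------------------------------------------
# rate tables

def test_context_rate_uniform(uniform_rates):
    assert context_rate(uniform_rates, "A", "G", "T", "C") == 1.0


def test_context_rate_transition_ratio():
    table = default_rate_table(4.0, 1.0)
    assert context_rate(table, "A", "G", "A", "T") == pytest.approx(
        4.0 * context_rate(table, "A", "G", "T", "T")
    )


def test_context_rate_rejects_identity(uniform_rates):
    with pytest.raises(ValueError):
        context_rate(uniform_rates, "A", "G", "G", "T")


def test_cpg_boost_is_strand_symmetric():
    table = default_rate_table(4.0, 10.0)
    assert context_rate(table, "A", "C", "T", "G") == pytest.approx(40.0)
    assert context_rate(table, "C", "G", "A", "T") == pytest.approx(40.0)
    assert symmetrize(table).rates == pytest.approx(table.rates)


def test_rate_table_completeness():
    with pytest.raises(ValueError, match="192"):
        RateTable({("A", "C", "T", "G"): 1.0})


def test_rate_table_file_round_trip(tmp_path):
    table = default_rate_table()
    path = tmp_path / "rates.tsv"
    write_rate_table(table, path, comment="round trip")
    again = read_rate_table(path)
    assert again.rates == pytest.approx(table.rates)
    # a stranded table skips symmetrization
    asym = dict(table.rates)
    asym[("A", "C", "T", "G")] = 99.0
    write_rate_table(RateTable(asym, stranded=True), path)
    loaded = read_rate_table(path)
    assert loaded.stranded
    assert loaded.rates[("A", "C", "T", "G")] == 99.0


# ---------------------------------------------------------------------------
# expected boundary fraction

def test_expected_fraction_uniform_identical_codons(uniform_rates):
    """10 Gly, 2 of them boundary, identical codons: mass cancels to 0.2."""
    arch = _toy_gly_arch(10)
    assert expected_boundary_fraction(arch, _cds_all_ggt(arch), uniform_rates) == pytest.approx(0.2)


def test_expected_fraction_scale_invariant(neighbour_rates):
    arch = _toy_gly_arch(10)
    cds = _cds_all_ggt(arch)
    scaled = RateTable(
        {key: 7.0 * value for key, value in neighbour_rates.rates.items()},
        stranded=neighbour_rates.stranded,
    )
    assert expected_boundary_fraction(arch, cds, scaled) == pytest.approx(
        expected_boundary_fraction(arch, cds, neighbour_rates)
    )


def test_expected_fraction_matches_exhaustive_enumeration(uniform_rates):
    """Oracle: brute-force every SNV of a <=300 nt toy CDS with random codons."""
    rng = np.random.default_rng(31)
    arch = build_architecture(
        [
            ("amino_terminus", 1, 4),
            ("collagenous", 5, 19),
            ("interruption", 20, 23),
            ("collagenous", 24, 44),
            ("carboxyl_terminus", 45, 50),
        ]
    )
    gly = {r for r, _, _ in gly_positions(arch)}
    gly_codons = ["GGA", "GGC", "GGG", "GGT"]
    other = ["CCT", "ACA", "TCC", "CTG"]
    cds = "".join(
        gly_codons[rng.integers(4)] if r in gly else other[rng.integers(4)]
        for r in range(1, arch.length + 1)
    )
    assert len(cds) <= 300

    boundary_snvs = total_snvs = 0
    translate = _standard_translate
    for residue in sorted(gly):
        start = 3 * (residue - 1)
        codon = cds[start : start + 3]
        is_boundary = classify_position(arch, residue) is GlyPositionClass.NC_BOUNDARY
        for i in range(3):
            for alt in "ACGT":
                if alt == codon[i]:
                    continue
                product = translate(codon[:i] + alt + codon[i + 1 :])
                if product in ("*", "G"):
                    continue
                total_snvs += 1
                boundary_snvs += is_boundary
    assert expected_boundary_fraction(arch, cds, uniform_rates) == pytest.approx(
        boundary_snvs / total_snvs, abs=1e-12
    )
    sites = enumerate_gly_missense(arch, cds, uniform_rates)
    assert len(sites) == total_snvs


def _standard_translate(codon):
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def test_expected_fraction_rejects_mismatched_cds(uniform_rates):
    arch = _toy_gly_arch(4)
    with pytest.raises(ValueError):
        expected_boundary_fraction(arch, "ATG" * arch.length, uniform_rates)
    with pytest.raises(ValueError):
        expected_boundary_fraction(arch, "GGT" * (arch.length - 1), uniform_rates)


def test_expected_fraction_on_chain_scale(col4a5_like_arch, col4a5_like_cds, neighbour_rates, uniform_rates):
    """On the full synthetic chain the weighted expectation stays near the
    unweighted SNV share and within [0, 1]."""
    weighted = expected_boundary_fraction(col4a5_like_arch, col4a5_like_cds, neighbour_rates)
    unweighted = expected_boundary_fraction(col4a5_like_arch, col4a5_like_cds, uniform_rates)
    assert 0.0 < weighted < 1.0
    assert abs(weighted - unweighted) < 0.05


# ---------------------------------------------------------------------------
# exact binomial test

@pytest.mark.parametrize(
    "k, n, p0, alternative, expected",
    [
        (1, 1, 0.5, "greater", 0.5),
        (0, 20, 0.3, "greater", 1.0),
    ],
)
def test_exact_binomial_closed_forms(k, n, p0, alternative, expected):
    assert exact_binomial(k, n, p0, alternative) == pytest.approx(expected, abs=1e-12)


def test_exact_binomial_overrepresentation():
    assert exact_binomial(15, 45, 0.101, "greater") < 0.001
    assert exact_binomial(15, 45, 0.101, "two_sided") < 0.001


def test_exact_binomial_matches_independent_implementations():
    """Survival-function identities and scipy's binomtest, n up to 1000."""
    from scipy.stats import binomtest

    rng = np.random.default_rng(41)
    for _ in range(25):
        n = int(rng.integers(1, 1001))
        k = int(rng.integers(0, n + 1))
        p0 = float(rng.uniform(0.01, 0.99))
        # closed-form tails via the survival function, independent of summation
        assert exact_binomial(k, n, p0, "greater") == pytest.approx(
            float(binom.sf(k - 1, n, p0)), abs=1e-12
        )
        assert exact_binomial(k, n, p0, "less") == pytest.approx(
            float(binom.cdf(k, n, p0)), abs=1e-12
        )
        assert exact_binomial(k, n, p0, "greater") == pytest.approx(
            binomtest(k, n, p0, alternative="greater").pvalue, abs=1e-12
        )
        # scipy's two-sided minimum-likelihood definition matches ours
        assert exact_binomial(k, n, p0, "two_sided") == pytest.approx(
            binomtest(k, n, p0, alternative="two-sided").pvalue, abs=1e-9
        )


@given(
    n=st.integers(min_value=1, max_value=200),
    data=st.data(),
)
def test_binomial_tail_complement_identity(n, data):
    k = data.draw(st.integers(min_value=0, max_value=n))
    p0 = data.draw(st.floats(min_value=0.05, max_value=0.95))
    total = exact_binomial(k, n, p0, "greater") + exact_binomial(k, n, p0, "less")
    mass_k = float(binom.pmf(k, n, p0))
    assert total == pytest.approx(1.0 + mass_k, abs=1e-10)


def test_exact_binomial_domain_errors():
    with pytest.raises(ValueError):
        exact_binomial(5, 4, 0.5)
    with pytest.raises(ValueError):
        exact_binomial(1, 4, 1.0)


# ---------------------------------------------------------------------------
# allele counting and prevalence

@pytest.mark.parametrize(
    "hem, het, hom, expected",
    [(249, 442, 7, 705), (4, 3, 0, 7), (0, 0, 0, 0), (2, 3, 1, 7)],
)
def test_allele_total(hem, het, hom, expected):
    assert allele_total(hem, het, hom) == expected


@given(
    a=st.integers(min_value=0, max_value=10_000),
    b=st.integers(min_value=0, max_value=10_000),
    c=st.integers(min_value=0, max_value=10_000),
)
def test_allele_total_linear(a, b, c):
    assert allele_total(a, b, c) == (
        allele_total(a, 0, 0) + allele_total(0, b, 0) + allele_total(0, 0, c)
    )


def test_allele_total_rejects_negative():
    with pytest.raises(ValueError):
        allele_total(-1, 0, 0)


def test_carrier_prevalence_counts_homozygotes_once():
    result = carrier_prevalence(
        [AlleleRecord("GlyX", 2, 3, 1)], population=(1000, 1000)
    )
    assert result.carrier_count == 6
    assert result.prevalence == pytest.approx(0.003)
    assert result.one_in == 333


def test_carrier_prevalence_empty():
    result = carrier_prevalence([], population=(10, 10))
    assert result.prevalence == 0.0 and result.one_in is None


def test_carrier_prevalence_consistency_error():
    with pytest.raises(ValueError, match="exceed"):
        carrier_prevalence([AlleleRecord("GlyX", 30, 0, 0)], population=(10, 10))


def test_bundled_allele_table_round_trip():
    from col4gly import data_path

    records = read_allele_table(data_path("gnomad_top5_boundary_alleles.tsv"))
    totals = {r.variant_label: r.total_alleles for r in records}
    assert totals == {
        "Gly953Val": 705,
        "Gly624Asp": 16,
        "Gly626Ser": 7,
        "Gly1074Ser": 7,
        "Gly961Val": 5,
    }
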