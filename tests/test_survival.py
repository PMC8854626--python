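"""Extraction rules, Kaplan-Meier, log-rank and Cox stage."""

import numpy as np
import pandas as pd
import pytest

from col4gly.survival import (
    DegenerateCovariateError,
    ExtractionError,
    FamilyObservation,
    IndividualRecord,
    aggregate_family,
    aggregate_registry,
    cox_fit,
    km_fit,
    logrank_test,
    observations_frame,
    phenotype_keyword_filter,
)


def _record(family="F1", sex="male", text="ESRD", **kwargs):
    return IndividualRecord(family_id=family, sex=sex, phenotype_text=text, **kwargs)


def _observations(pairs):
    return [
        FamilyObservation(f"F{i}", time, event)
        for i, (time, event) in enumerate(pairs)
    ]


# ---------------------------------------------------------------------------
# extraction

@pytest.mark.parametrize(
    "text, endpoint, kept",
    [
        ("ESRD at 25", "kidney", True),
        ("commenced Dialysis aged 30", "kidney", True),
        ("received a renal transplant", "kidney", True),
        ("isolated haematuria", "kidney", False),
        ("Sensorineural deafness", "hearing", True),
        ("bilateral hypoacusia", "hearing", True),
        ("normal audiometry", "hearing", True),  # 'audio' keyword
        ("isolated haematuria", "hearing", False),
    ],
)
def test_phenotype_keyword_filter(text, endpoint, kept):
    records = [_record(text=text, event_age=20.0)]
    assert bool(phenotype_keyword_filter(records, endpoint)) is kept


def test_keyword_filter_unknown_endpoint():
    with pytest.raises(ValueError):
        phenotype_keyword_filter([], "ocular")


def test_aggregate_mean_of_male_events():
    obs = aggregate_family(
        [_record(event_age=20.0), _record(event_age=30.0)]
    )
    assert obs.time == 25.0 and obs.event is True


def test_aggregate_range_midpoint():
    obs = aggregate_family([_record(event_age_range=(20.0, 30.0))])
    assert obs.time == 25.0 and obs.event is True


def test_aggregate_censored_at_latest_report():
    obs = aggregate_family(
        [_record(last_seen_age=40.0), _record(last_seen_age=35.0)]
    )
    assert obs.time == 40.0 and obs.event is False


def test_aggregate_ignores_female_ages():
    with pytest.raises(ExtractionError, match="no male"):
        aggregate_family([_record(sex="female", event_age=25.0)])


def test_aggregate_registry_excludes_multivariant_carriers():
    records = [
        _record(family="F1", event_age=25.0, variant_ids=("Gly100Val",)),
        _record(family="F2", event_age=30.0, variant_ids=("Gly100Val", "Gly200Asp")),
    ]
    observations, exclusions = aggregate_registry(records, "kidney")
    assert [o.family_id for o in observations] == ["F1"]
    assert exclusions["multi_variant"] == ["F2"]


# ---------------------------------------------------------------------------
# Kaplan-Meier against hand product-limit computation

def test_km_single_event():
    curve = km_fit(_observations([(26.0, True)]))
    assert curve.median == 26.0
    assert curve.survival.tolist() == [0.0]


def test_km_hand_product_limit():
    # events at 10 and 30, censored at 20:
    # S(10) = 1 - 1/3 = 2/3; S(30) = 2/3 * (1 - 1/1) = 0
    curve = km_fit(_observations([(10.0, True), (20.0, False), (30.0, True)]))
    assert curve.times.tolist() == [10.0, 30.0]
    assert curve.survival == pytest.approx([2.0 / 3.0, 0.0])
    assert curve.median == 30.0


def test_km_hand_product_limit_with_ties():
    # n=5: events at 5 (x2), censor at 7, event at 10, censor at 12
    # S(5) = 3/5; S(10) = 3/5 * (1 - 1/2) = 3/10
    curve = km_fit(
        _observations(
            [(5.0, True), (5.0, True), (7.0, False), (10.0, True), (12.0, False)]
        )
    )
    assert curve.survival == pytest.approx([0.6, 0.3])
    assert curve.median == 10.0


def test_km_median_exponential_recovery():
    rng = np.random.default_rng(11)
    rate = np.log(2.0) / 26.0
    times = rng.exponential(1.0 / rate, size=500)
    curve = km_fit([FamilyObservation(f"F{i}", t, True) for i, t in enumerate(times)])
    assert 24.0 <= curve.median <= 28.0


def test_km_median_equals_sample_median_without_censoring():
    rng = np.random.default_rng(3)
    for _ in range(20):
        times = rng.uniform(1.0, 50.0, size=int(rng.integers(3, 12)))
        curve = km_fit([FamilyObservation(f"F{i}", t, True) for i, t in enumerate(times)])
        ordered = np.sort(times)
        n = len(ordered)
        # smallest observation with S <= 0.5: element ceil(n/2) - 1 (0-based)
        expected = ordered[int(np.ceil(n / 2)) - 1]
        assert curve.median == pytest.approx(expected)


def test_km_invariants_and_nd_bounds():
    rng = np.random.default_rng(5)
    times = rng.exponential(30.0, size=40)
    events = rng.random(40) < 0.3  # mostly censored: median may be unreached
    curve = km_fit(
        [FamilyObservation(f"F{i}", t, bool(e)) for i, (t, e) in enumerate(zip(times, events))]
    )
    assert np.all(np.diff(curve.survival) <= 1e-12)
    assert np.all((curve.survival >= 0) & (curve.survival <= 1))
    assert np.all(curve.ci_low <= curve.survival + 1e-12)
    assert np.all(curve.ci_high >= curve.survival - 1e-12)
    report = curve.as_report()
    if curve.median is None:
        assert report["median"] == "ND"


def test_km_rejects_bad_input():
    with pytest.raises(ValueError):
        km_fit([])


# ---------------------------------------------------------------------------
# log-rank

def test_logrank_identical_groups():
    base = [(10.0, True), (20.0, False), (30.0, True)]
    observations = _observations(base) + _observations(base)
    groups = [0, 0, 0, 1, 1, 1]
    stat, df, p = logrank_test(groups, observations)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert df == 1
    assert p == pytest.approx(1.0)


def test_logrank_requires_two_groups():
    with pytest.raises(ValueError):
        logrank_test([0, 0], _observations([(1.0, True), (2.0, True)]))


def test_logrank_detects_strong_effect():
    rng = np.random.default_rng(9)
    hits = 0
    for rep in range(50):
        t0 = rng.exponential(30.0, size=100)
        t1 = rng.exponential(10.0, size=100)  # hazard ratio 3
        observations = [
            FamilyObservation(f"A{i}", t, True) for i, t in enumerate(t0)
        ] + [FamilyObservation(f"B{i}", t, True) for i, t in enumerate(t1)]
        _, _, p = logrank_test([0] * 100 + [1] * 100, observations)
        hits += p < 0.05
    assert hits >= 48  # >= 95% power at HR 3, n=100/group


def test_logrank_equals_cox_score_test_two_groups():
    """On 2 untied groups the log-rank statistic is the Cox score test."""
    rng = np.random.default_rng(21)
    times = np.round(rng.exponential(20.0, size=60), 6)
    assert len(set(times)) == 60  # no ties
    groups = rng.integers(0, 2, size=60)
    observations = [
        FamilyObservation(f"F{i}", t, True) for i, t in enumerate(times)
    ]
    stat, _, _ = logrank_test(groups.tolist(), observations)

    # independent score-test computation from the risk sets
    order = np.argsort(times)
    score = 0.0
    information = 0.0
    for position, i in enumerate(order):
        at_risk = order[position:]
        x = groups[at_risk]
        mean = x.mean()
        score += groups[i] - mean
        information += np.mean((x - mean) ** 2)
    assert stat == pytest.approx(score**2 / information, abs=1e-6)


# ---------------------------------------------------------------------------
# Cox model

def _ph_frame(rng, n, log_hr):
    covariate = rng.integers(0, 2, size=n)
    rate = (np.log(2.0) / 26.0) * np.exp(log_hr * covariate)
    times = rng.exponential(1.0 / rate)
    censor = rng.uniform(10.0, 80.0, size=n)
    return pd.DataFrame(
        {
            "time": np.minimum(times, censor),
            "event": times <= censor,
            "x": covariate,
        }
    )


def test_cox_parameter_recovery():
    # the log-HR estimate at n=150 has sampling SE ~0.2, so recovery is
    # judged on the mean over 10 fixed-seed replicates
    estimates = []
    for seed in range(10):
        frame = _ph_frame(np.random.default_rng(130 + seed), 150, 0.7)
        result = cox_fit(frame, ["x"])
        estimates.append(result.log_hr["x"])
        assert result.ci_low["x"] < result.hazard_ratio["x"] < result.ci_high["x"]
    assert abs(np.mean(estimates) - 0.7) < 0.25
    assert result.lr_p < 0.05


def test_cox_null_coverage():
    rng = np.random.default_rng(17)
    covered = 0
    for _ in range(100):
        frame = _ph_frame(rng, 200, 0.0)
        result = cox_fit(frame, ["x"])
        covered += result.ci_low["x"] <= 1.0 <= result.ci_high["x"]
    assert covered >= 90


def test_cox_degenerate_covariate():
    frame = pd.DataFrame(
        {"time": [1.0, 2.0, 3.0], "event": [True, True, True], "x": [1, 1, 1]}
    )
    with pytest.raises(DegenerateCovariateError):
        cox_fit(frame, ["x"])


def test_cox_requires_events():
    frame = pd.DataFrame(
        {"time": [1.0, 2.0], "event": [False, True], "x": [0, 1]}
    )
    with pytest.raises(ValueError):
        cox_fit(frame, ["x"])


def test_observations_frame_columns():
    observations = [
        FamilyObservation("F1", 10.0, True, {"is_nc_boundary": 1}),
        FamilyObservation("F2", 20.0, False, {"is_nc_boundary": 0}),
    ]
    frame = observations_frame(observations)
    assert list(frame.columns) == ["family_id", "time", "event", "is_nc_boundary"]
    assert frame["is_nc_boundary"].tolist() == [1, 0]
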