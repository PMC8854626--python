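"""Time-to-event analysis of kidney failure and hearing-loss diagnosis.

The registry data this stage consumes are family-level reports: free-text
phenotype entries with ages at kidney failure (diagnosis, first dialysis
or first transplant) or at hearing-loss diagnosis in affected males.
Records pass a keyword screen per endpoint, then each family is collapsed
to a single observation — mean event age across affected males (a lone
reported median stands in as the value, and a reported range contributes
its midpoint), or a censoring age at the latest report when no male has
reached the endpoint.  Families with only affected females, and
individuals carrying more than one COL4A3-COL4A5 variant, are excluded.

Estimation is Kaplan-Meier with Greenwood variance and log-transformed
pointwise 95% intervals, group comparison by the log-rank test, and
covariate effects by a Cox proportional-hazards model with Efron tie
handling and a likelihood-ratio test of the overall model.  The numerical
machinery is provided by ``lifelines``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "IndividualRecord",
    "FamilyObservation",
    "SurvivalCurve",
    "CoxResult",
    "ExtractionError",
    "DegenerateCovariateError",
    "KIDNEY_KEYWORDS",
    "HEARING_KEYWORDS",
    "phenotype_keyword_filter",
    "aggregate_family",
    "aggregate_registry",
    "km_fit",
    "logrank_test",
    "cox_fit",
    "observations_frame",
]

KIDNEY_KEYWORDS = (
    "renal",
    "failure",
    "esrd",
    "esrf",
    "eskd",
    "eskf",
    "transplant",
    "dialysis",
)
HEARING_KEYWORDS = ("hearing", "hypoacusia", "deaf", "sensorineural", "audio")

_KEYWORDS_BY_ENDPOINT = {"kidney": KIDNEY_KEYWORDS, "hearing": HEARING_KEYWORDS}


class ExtractionError(ValueError):
    """A family yields no usable event or censoring age."""


class DegenerateCovariateError(ValueError):
    """A covariate takes a single value and cannot be fitted."""


@dataclass(frozen=True)
class IndividualRecord:
    family_id: str
    sex: str  # 'male' | 'female'
    phenotype_text: str
    event_age: float | None = None
    event_age_range: tuple[float, float] | None = None
    last_seen_age: float | None = None
    variant_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (
            self.event_age is None
            and self.event_age_range is None
            and self.last_seen_age is None
        ):
            raise ValueError(
                f"record in family {self.family_id} has no event or censoring age"
            )


@dataclass(frozen=True)
class FamilyObservation:
    family_id: str
    time: float
    event: bool
    features: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"family {self.family_id}: non-positive time {self.time}")


def phenotype_keyword_filter(
    records: list[IndividualRecord], endpoint: str
) -> list[IndividualRecord]:
    """Keep records whose free text mentions any endpoint keyword (case-insensitive)."""
    if endpoint not in _KEYWORDS_BY_ENDPOINT:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected 'kidney' or 'hearing'")
    keywords = _KEYWORDS_BY_ENDPOINT[endpoint]
    return [
        r for r in records if any(k in r.phenotype_text.lower() for k in keywords)
    ]


def _event_age(record: IndividualRecord) -> float | None:
    if record.event_age is not None:
        return float(record.event_age)
    if record.event_age_range is not None:
        low, high = record.event_age_range
        return (float(low) + float(high)) / 2.0  # midpoint of a reported range
    return None


def aggregate_family(
    records: list[IndividualRecord], features: dict | None = None
) -> FamilyObservation:
    """Collapse one family's male records into a single observation.

    Event ages of affected males are averaged (a reported range enters as
    its midpoint; a lone reported median is simply the record's age value).
    Families without any event are censored at the latest last-seen age
    among the males.
    """
    if not records:
        raise ExtractionError("empty family")
    family_id = records[0].family_id
    males = [r for r in records if r.sex.lower().startswith("m")]
    if not males:
        raise ExtractionError(f"family {family_id}: no male records")
    event_ages = [age for age in (_event_age(r) for r in males) if age is not None]
    if event_ages:
        return FamilyObservation(
            family_id, float(np.mean(event_ages)), True, features or {}
        )
    censor_ages = [r.last_seen_age for r in males if r.last_seen_age is not None]
    if not censor_ages:
        raise ExtractionError(f"family {family_id}: no usable age in any male record")
    return FamilyObservation(family_id, float(max(censor_ages)), False, features or {})


def aggregate_registry(
    records: list[IndividualRecord],
    endpoint: str,
    features_by_family: dict[str, dict] | None = None,
) -> tuple[list[FamilyObservation], dict[str, list[str]]]:
    """Apply the endpoint keyword screen and family aggregation to a registry.

    Each family contributes once.  Exclusions (with family ids) are
    returned alongside the observations: ``multi_variant`` for families
    whose males carry more than one distinct variant, ``female_only`` for
    families with no male record, ``no_usable_age`` when no age can be
    extracted.
    """
    kept = phenotype_keyword_filter(records, endpoint)
    exclusions: dict[str, list[str]] = {
        "multi_variant": [],
        "female_only": [],
        "no_usable_age": [],
    }
    observations: list[FamilyObservation] = []
    by_family: dict[str, list[IndividualRecord]] = {}
    for record in kept:
        by_family.setdefault(record.family_id, []).append(record)
    for family_id, family_records in by_family.items():
        if any(len(r.variant_ids) > 1 for r in family_records):
            exclusions["multi_variant"].append(family_id)
            continue
        try:
            features = (features_by_family or {}).get(family_id, {})
            observations.append(aggregate_family(family_records, features))
        except ExtractionError as exc:
            key = "female_only" if "no male" in str(exc) else "no_usable_age"
            exclusions[key].append(family_id)
    return observations, exclusions


def observations_frame(observations: list[FamilyObservation]) -> pd.DataFrame:
    """Tidy frame with time, event and one column per feature."""
    rows = []
    for obs in observations:
        row = {"family_id": obs.family_id, "time": obs.time, "event": obs.event}
        row.update(obs.features)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass(frozen=True)
class SurvivalCurve:
    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    median: float | None
    median_ci: tuple[float | None, float | None]
    n: int
    n_events: int

    def as_report(self) -> dict:
        nd = lambda value: "ND" if value is None else value  # noqa: E731
        return {
            "n": self.n,
            "n_events": self.n_events,
            "median": nd(self.median),
            "median_ci": [nd(self.median_ci[0]), nd(self.median_ci[1])],
            "times": self.times.tolist(),
            "survival": self.survival.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
        }


def km_fit(observations: list[FamilyObservation], alpha: float = 0.05) -> SurvivalCurve:
    """Product-limit estimate with Greenwood log-transformed pointwise CI.

    The median is the smallest time at which the estimate falls to 0.5 or
    below (``None`` when never reached); its confidence interval inverts
    the pointwise interval, with unreached bounds reported as ``None``
    ("ND" in serialized reports).
    """
    if not observations:
        raise ValueError("no observations")
    times = np.array([obs.time for obs in observations], dtype=float)
    events = np.array([obs.event for obs in observations], dtype=bool)
    if np.any(times <= 0):
        raise ValueError("non-positive observation times")

    fitter = KaplanMeierFitter()
    fitter.fit(times, events)
    table = fitter.event_table  # at_risk, observed per distinct time
    event_rows = table[table["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    d = event_rows["observed"].to_numpy(dtype=float)
    n_at_risk = event_rows["at_risk"].to_numpy(dtype=float)
    survival = np.cumprod(1.0 - d / n_at_risk)

    # Greenwood variance of log S, log-transformed 95% bounds: S * exp(+-z*sigma)
    from scipy.stats import norm

    z = norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        increments = np.where(
            n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf
        )
        sigma = np.sqrt(np.cumsum(increments))
        ci_low = np.clip(survival * np.exp(-z * sigma), 0.0, 1.0)
        ci_high = np.clip(survival * np.exp(z * sigma), 0.0, 1.0)
    ci_low = np.where(survival == 0.0, 0.0, ci_low)
    ci_high = np.where(survival == 0.0, 0.0, ci_high)

    def first_time_at_or_below(values: np.ndarray, level: float) -> float | None:
        hits = np.nonzero(values <= level)[0]
        return float(event_times[hits[0]]) if hits.size else None

    median = first_time_at_or_below(survival, 0.5)
    median_ci = (
        first_time_at_or_below(ci_high, 0.5),  # lower bound: upper band crosses first
        first_time_at_or_below(ci_low, 0.5),
    )
    return SurvivalCurve(
        times=event_times,
        survival=survival,
        ci_low=ci_low,
        ci_high=ci_high,
        median=median,
        median_ci=median_ci,
        n=len(observations),
        n_events=int(events.sum()),
    )


def logrank_test(
    group_assignments: list, observations: list[FamilyObservation]
) -> tuple[float, int, float]:
    """Log-rank comparison of k survival curves: (chi-square, df, p)."""
    if len(group_assignments) != len(observations):
        raise ValueError("one group label per observation required")
    groups = pd.Series(group_assignments)
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two non-empty groups")
    times = np.array([obs.time for obs in observations], dtype=float)
    events = np.array([obs.event for obs in observations], dtype=bool)
    result = multivariate_logrank_test(times, groups.to_numpy(), events)
    df = len(counts) - 1
    return float(result.test_statistic), df, float(result.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards

@dataclass(frozen=True)
class CoxResult:
    covariates: tuple[str, ...]
    log_hr: dict[str, float]
    hazard_ratio: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    wald_p: dict[str, float]
    se: dict[str, float]
    lr_p: float
    lr_statistic: float
    n: int
    n_events: int

    def as_report(self) -> dict:
        return {
            "n": self.n,
            "n_events": self.n_events,
            "likelihood_ratio_p": self.lr_p,
            "terms": {
                name: {
                    "log_hr": self.log_hr[name],
                    "hr": self.hazard_ratio[name],
                    "hr_ci": [self.ci_low[name], self.ci_high[name]],
                    "se": self.se[name],
                    "wald_p": self.wald_p[name],
                }
                for name in self.covariates
            },
        }


def cox_fit(frame: pd.DataFrame, covariates: list[str]) -> CoxResult:
    """Cox proportional-hazards fit (Efron tie handling).

    ``frame`` needs ``time`` and ``event`` columns plus the covariates.
    Raises :class:`DegenerateCovariateError` for a constant covariate and
    ``ValueError`` with the event count when fewer than two events exist.
    """
    n_events = int(frame["event"].sum())
    if n_events < 2:
        raise ValueError(f"need at least 2 events, got {n_events}")
    for name in covariates:
        if frame[name].nunique() < 2:
            raise DegenerateCovariateError(f"covariate {name!r} does not vary")
    fitter = CoxPHFitter()
    fitter.fit(
        frame[["time", "event"] + list(covariates)],
        duration_col="time",
        event_col="event",
    )
    summary = fitter.summary
    lr = fitter.log_likelihood_ratio_test()
    return CoxResult(
        covariates=tuple(covariates),
        log_hr={c: float(summary.loc[c, "coef"]) for c in covariates},
        hazard_ratio={c: float(summary.loc[c, "exp(coef)"]) for c in covariates},
        ci_low={c: float(summary.loc[c, "exp(coef) lower 95%"]) for c in covariates},
        ci_high={c: float(summary.loc[c, "exp(coef) upper 95%"]) for c in covariates},
        wald_p={c: float(summary.loc[c, "p"]) for c in covariates},
        se={c: float(summary.loc[c, "se(coef)"]) for c in covariates},
        lr_p=float(lr.p_value),
        lr_statistic=float(lr.test_statistic),
        n=int(len(frame)),
        n_events=n_events,
    )
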