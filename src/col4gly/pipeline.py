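"""End-to-end orchestration: annotate, screen, analyse, report.

The pipeline wires the stages together over plain tab-separated inputs:
variants are annotated against a chain architecture, anything flagged by
the splice screen is excluded (with a machine-readable reason), families
or individuals carrying multiple variants are excluded, and the surviving
observations flow into the survival, haematuria or population stage.  A
run manifest reconciles every count: records read = analyzed + the sum of
all exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import haematuria as hm
from . import population as pop
from . import survival as sv
from .chain_model import ChainArchitecture, GlyPositionClass
from .io import write_report
from .variants import VariantAnnotation, annotate, parse_cdna, parse_protein

__all__ = [
    "RunManifest",
    "annotate_variant_table",
    "features_from_annotation",
    "survival_analysis",
    "haematuria_analysis",
    "population_analysis",
]

SIGNIFICANCE_LEVEL = 0.05  # reported alongside estimates, never used to drop them


@dataclass
class RunManifest:
    """Audit record of one pipeline run; counts must reconcile."""

    seed: int | None
    stage: str
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    n_read: int = 0
    exclusions: dict = field(default_factory=dict)  # reason -> list of ids
    n_analyzed: int = 0

    def exclude(self, reason: str, identifier: str) -> None:
        self.exclusions.setdefault(reason, []).append(identifier)

    @property
    def reconciles(self) -> bool:
        return self.n_read == self.n_analyzed + sum(
            len(ids) for ids in self.exclusions.values()
        )

    def as_report(self) -> dict:
        return {
            "seed": self.seed,
            "stage": self.stage,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "n_read": self.n_read,
            "n_analyzed": self.n_analyzed,
            "exclusions": {k: sorted(v) for k, v in self.exclusions.items()},
            "reconciles": self.reconciles,
        }


def features_from_annotation(annotation: VariantAnnotation) -> dict:
    """The binary feature vector the regression stages consume."""
    return {
        "is_nc_boundary": int(annotation.is_nc_boundary),
        "is_high_destab": int(annotation.is_high_destab),
        "is_carboxyl_block": int(not annotation.is_amino_block),
        "is_amino_end": int(annotation.position_class is GlyPositionClass.AMINO_END),
        "is_carboxyl_end": int(annotation.position_class is GlyPositionClass.CARBOXYL_END),
    }


def annotate_variant_table(
    arch: ChainArchitecture, frame: pd.DataFrame
) -> pd.DataFrame:
    """Append annotation columns to a variant table (gene, protein_hgvs[, cdna_hgvs])."""
    rows = []
    for _, row in frame.iterrows():
        protein = parse_protein(str(row["protein_hgvs"]))
        cdna_text = str(row.get("cdna_hgvs") or "").strip()
        cdna = parse_cdna(cdna_text) if cdna_text and cdna_text.lower() != "nan" else None
        annotation = annotate(arch, protein, cdna)
        extra = {
            "position_class": annotation.position_class.value,
            "boundary_side": annotation.boundary_side or "",
            "exon_index": annotation.exon_index,
            "local_region_ordinal": annotation.local_region_ordinal,
            "destab_class": annotation.destab_class,
            **features_from_annotation(annotation),
        }
        rows.append({**row.to_dict(), **extra})
    return pd.DataFrame(rows)


def _annotation_for_label(arch: ChainArchitecture, label: str) -> VariantAnnotation:
    return annotate(arch, parse_protein(label))


def _splice_flagged(value) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes"}


def survival_analysis(
    records: list[sv.IndividualRecord],
    arch: ChainArchitecture,
    endpoint: str = "kidney",
    manifest: RunManifest | None = None,
    splice_flagged_variants: set[str] = frozenset(),
) -> dict:
    """Family-level survival analysis of one endpoint.

    Each family's variant label (from ``variant_ids``) is annotated on the
    chain; splice-flagged variants and multi-variant carriers are
    excluded; Kaplan-Meier curves, log-rank tests and the Cox model are
    fitted per molecular feature, then the local-region subgroup
    (boundary carriers dropped, end-position covariates) is refitted with
    the identical aggregation.
    """
    manifest = manifest or RunManifest(seed=None, stage=f"survival_{endpoint}")
    all_families = sorted({r.family_id for r in records})
    manifest.n_read = len(all_families)  # one unit per family throughout

    kept = sv.phenotype_keyword_filter(records, endpoint)
    kept_families = {r.family_id for r in kept}
    for family_id in all_families:
        if family_id not in kept_families:
            manifest.exclude("no_endpoint_keyword", family_id)

    splice_excluded = {
        r.family_id
        for r in kept
        if any(v in splice_flagged_variants for v in r.variant_ids)
    }
    for family_id in sorted(splice_excluded):
        manifest.exclude("splice_predicted", family_id)
    usable = [r for r in kept if r.family_id not in splice_excluded]

    features_by_family = {}
    for family_id in sorted({r.family_id for r in usable}):
        labels = {
            v for r in usable if r.family_id == family_id for v in r.variant_ids
        }
        if len(labels) != 1:  # distinct variants across the family's records
            manifest.exclude("multi_variant", family_id)
            continue
        annotation = _annotation_for_label(arch, labels.pop())
        features_by_family[family_id] = features_from_annotation(annotation)
    usable = [r for r in usable if r.family_id in features_by_family]

    observations, exclusions = sv.aggregate_registry(
        usable, endpoint, features_by_family
    )
    for reason, ids in exclusions.items():
        for family_id in ids:
            manifest.exclude(reason, family_id)
    manifest.n_analyzed = len(observations)

    frame = sv.observations_frame(observations)
    report: dict = {"endpoint": endpoint, "n_families": len(observations)}
    report["overall"] = sv.km_fit(observations).as_report()
    for feature in ("is_carboxyl_block", "is_nc_boundary", "is_high_destab"):
        groups = frame[feature].tolist()
        strata = {}
        for level in sorted(set(groups)):
            subset = [o for o, g in zip(observations, groups) if g == level]
            strata[str(level)] = sv.km_fit(subset).as_report()
        stat, df, p = sv.logrank_test(groups, observations)
        report[feature] = {"strata": strata, "logrank": {"chi2": stat, "df": df, "p": p}}
    report["cox_all"] = sv.cox_fit(
        frame, ["is_carboxyl_block", "is_nc_boundary", "is_high_destab"]
    ).as_report()

    subgroup = frame[frame["is_nc_boundary"] == 0]
    if subgroup["event"].sum() >= 2:
        report["cox_local_region"] = sv.cox_fit(
            subgroup,
            ["is_carboxyl_block", "is_amino_end", "is_carboxyl_end", "is_high_destab"],
        ).as_report()
    report["manifest"] = manifest.as_report()
    return report


def haematuria_analysis(
    cohort: pd.DataFrame,
    arch: ChainArchitecture | None = None,
    exclude_variants: tuple[str, ...] = (),
    manifest: RunManifest | None = None,
) -> dict:
    """Logistic stage with sensitivity exclusion and local-region subgroup.

    The cohort needs ``outcome`` and either precomputed feature columns or
    a ``protein_hgvs`` column plus an architecture to annotate against.
    Individuals flagged by the splice screen (``splice_flagged`` column)
    or carrying multiple qualifying variants (semicolon-separated labels)
    are excluded before fitting.
    """
    manifest = manifest or RunManifest(seed=None, stage="haematuria")
    manifest.n_read = len(cohort)
    cohort = cohort.copy()
    if "variant_label" not in cohort.columns and "protein_hgvs" in cohort.columns:
        cohort["variant_label"] = cohort["protein_hgvs"]

    keep = []
    rows = []
    for _, row in cohort.iterrows():
        identifier = str(row.get("individual_id", row.name))
        if "splice_flagged" in cohort.columns and _splice_flagged(row["splice_flagged"]):
            manifest.exclude("splice_predicted", identifier)
            continue
        labels = [v for v in str(row["variant_label"]).split(";") if v]
        if len(labels) > 1:
            manifest.exclude("multi_variant", identifier)
            continue
        if "is_nc_boundary" not in cohort.columns:
            if arch is None:
                raise ValueError("architecture required to derive features")
            annotation = _annotation_for_label(arch, labels[0])
            row = pd.Series({**row.to_dict(), **features_from_annotation(annotation)})
        keep.append(identifier)
        rows.append(row)
    analyzed = pd.DataFrame(rows).reset_index(drop=True)
    analyzed["outcome"] = analyzed["outcome"].astype(int)
    for column in ("is_nc_boundary", "is_high_destab", "is_carboxyl_block",
                   "is_amino_end", "is_carboxyl_end"):
        analyzed[column] = analyzed[column].astype(int)
    manifest.n_analyzed = len(analyzed)

    report: dict = {
        "n": len(analyzed),
        "n_cases": int(analyzed["outcome"].sum()),
    }
    def _fit_or_reason(frame: pd.DataFrame, terms) -> dict:
        # a subgroup or sensitivity cohort can be too sparse to fit
        # (separated or constant term): report the reason, keep the run
        try:
            return hm.logistic_fit(frame, terms).as_report()
        except (hm.SeparationError, ValueError) as exc:
            return {"not_fitted": str(exc)}

    report["model_all"] = _fit_or_reason(analyzed, hm.DEFAULT_TERMS)
    subgroup, subgroup_terms = hm.subgroup_local_region(analyzed)
    report["model_local_region"] = _fit_or_reason(subgroup, subgroup_terms)
    if exclude_variants:
        reduced, n_removed = hm.sensitivity_exclude(analyzed, set(exclude_variants))
        report["sensitivity_excluded_variants"] = list(exclude_variants)
        report["sensitivity_n_removed"] = n_removed
        report["model_sensitivity"] = _fit_or_reason(reduced, hm.DEFAULT_TERMS)
    report["manifest"] = manifest.as_report()
    return report


def population_analysis(
    arch: ChainArchitecture,
    cds: str,
    rate_table: pop.RateTable,
    observed_boundary: int,
    observed_total: int,
    allele_records: list[pop.AlleleRecord] = (),
    population: tuple[int, int] | None = None,
    alternative: str = "greater",
    exclude_splice: bool = False,
) -> dict:
    """Observed vs expected boundary share, plus carrier prevalence."""
    expected = pop.expected_boundary_fraction(
        arch, cds, rate_table, exclude_splice=exclude_splice
    )
    report: dict = {
        "expected_boundary_fraction": expected,
        "observed_boundary": observed_boundary,
        "observed_total": observed_total,
        "observed_boundary_fraction": observed_boundary / observed_total,
        "binomial_alternative": alternative,
        "binomial_p": pop.exact_binomial(
            observed_boundary, observed_total, expected, alternative
        ),
        "exclude_splice": exclude_splice,
    }
    if allele_records:
        report["allele_totals"] = {
            record.variant_label: record.total_alleles for record in allele_records
        }
        if population is not None:
            report["carrier_prevalence"] = pop.carrier_prevalence(
                list(allele_records), population
            ).as_report()
    return report


def write_stage_report(report: dict, out_dir: str | Path, name: str) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.json"
    write_report(report, path)
    return path
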