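"""Cohort-level summaries and group comparisons.

Percentages are exposed both as raw floats and integer-truncated values
(clinical tables commonly truncate; both renderings are kept so either
convention can be reproduced). Group tests are the field-standard ones:
chi-square for categorical variables (no Yates correction by default)
and one-way ANOVA for continuous variables, via scipy.stats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .config import RunConfig
from .records import PatientRecord
from .terms import FeatureCatalog, load_catalog
from .triage import SuspicionResult


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class Freq:
    count: int
    denominator: int

    @property
    def percent(self) -> float:
        return 100.0 * self.count / self.denominator if self.denominator else 0.0

    @property
    def percent_truncated(self) -> int:
        return int(self.percent)


@dataclass
class CohortSummary:
    n: int
    sex_counts: dict[str, int]
    onset_category_counts: dict[str, Freq]
    onset_denominator: int
    beacon_counts: dict[str, int]
    primary_label_counts: dict[str, int]
    feature_group_prevalence: dict[str, Freq]
    per_group_feature_prevalence: dict[tuple[str, str], Freq]
    median_age_by_label: dict[str, float]
    transfusion_dependent_count: int
    pancytopenia_count: int
    complete_triad_count: int
    bm_biopsy_counts: dict[str, int]
    mortality_count: int = 0


@dataclass
class DescriptiveStats:
    n: int
    mean: float
    sd: Optional[float]
    median: float
    min: float
    max: float


@dataclass
class GroupTestReport:
    variable: str
    kind: Literal["categorical", "continuous"]
    test: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    groups: list[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def describe(values: Sequence[float]) -> DescriptiveStats:
    """Mean, sample SD (n−1; None for a single value), median (midpoint
    convention), min and max."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise CohortError("describe() needs at least one value")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else None
    return DescriptiveStats(
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sd=sd,
        median=float(np.median(arr)),
        min=float(np.min(arr)),
        max=float(np.max(arr)),
    )


_SPECIFIC = ("DBA", "SDS", "DC", "TAR", "SCN")

#: feature groups tabulated in the cohort summary, by organ-system root
SUMMARY_GROUPS = (
    "craniofacial", "neurological", "integument", "growth",
    "gastrointestinal", "skeletal", "genitourinary", "liver",
    "cardiac", "respiratory", "pancreatic",
)


def _align(cohort: Sequence[PatientRecord], results: Sequence[SuspicionResult]):
    by_id = {r.patient_id: r for r in results}
    if len(by_id) != len(results):
        raise CohortError("duplicate patient_id in results")
    missing = [r.patient_id for r in cohort if r.patient_id not in by_id]
    extra = set(by_id) - {r.patient_id for r in cohort}
    if missing or extra:
        raise CohortError(f"cohort/results id mismatch: missing={missing} extra={sorted(extra)}")
    return [(r, by_id[r.patient_id]) for r in cohort]


def _label(res: SuspicionResult) -> str:
    return res.primary if res.primary in _SPECIFIC else res.primary


def summarize(
    cohort: Sequence[PatientRecord],
    results: Sequence[SuspicionResult],
    catalog: FeatureCatalog | None = None,
    config: RunConfig = RunConfig(),
) -> CohortSummary:
    """Deterministic frequency tables over a classified cohort."""
    from .hematology import hematology_profile  # local to avoid cycle at import

    cat = catalog if catalog is not None else load_catalog()
    pairs = _align(cohort, results)
    n = len(pairs)

    sex_counts: dict[str, int] = {}
    label_counts: dict[str, int] = {}
    onset_counts: dict[str, int] = {}
    beacon_counts = {k: 0 for k in (
        "consanguinity", "endogamy", "isonymy", "family_hematologic",
        "personal_early_malignancy", "fgr_or_sga", "physical_alterations")}
    group_counts = {g: 0 for g in SUMMARY_GROUPS}
    per_group: dict[tuple[str, str], int] = {}
    label_n: dict[str, int] = {}
    ages_by_label: dict[str, list[float]] = {}
    td = pancyto = triad_complete = deaths = 0
    bm_counts: dict[str, int] = {}

    for record, res in pairs:
        profile = hematology_profile(record, cat, config.thresholds)
        label = _label(res)
        sex_counts[record.sex] = sex_counts.get(record.sex, 0) + 1
        label_counts[label] = label_counts.get(label, 0) + 1
        label_n[label] = label_n.get(label, 0) + 1
        ages_by_label.setdefault(label, []).append(record.age_years)
        if profile.onset_category != "none":
            onset_counts[profile.onset_category] = onset_counts.get(profile.onset_category, 0) + 1
        for name in beacon_counts:
            if getattr(res.beacons, name):
                beacon_counts[name] += 1
        systems = cat.organ_systems_hit(record.feature_ids)
        for g in SUMMARY_GROUPS:
            if g in systems:
                group_counts[g] += 1
                per_group[(label, g)] = per_group.get((label, g), 0) + 1
        if profile.transfusion_dependent:
            td += 1
        if profile.worst_class.value == "pancytopenia":
            pancyto += 1
        if len(cat.group_hits(record.feature_ids, "dc_triad")) == 3:
            triad_complete += 1
        for finding in record.labs.bm_biopsy:
            bm_counts[finding] = bm_counts.get(finding, 0) + 1

    onset_denom = sum(onset_counts.values())
    return CohortSummary(
        n=n,
        sex_counts=sex_counts,
        onset_category_counts={k: Freq(v, onset_denom) for k, v in sorted(onset_counts.items())},
        onset_denominator=onset_denom,
        beacon_counts=beacon_counts,
        primary_label_counts=dict(sorted(label_counts.items())),
        feature_group_prevalence={g: Freq(c, n) for g, c in group_counts.items()},
        per_group_feature_prevalence={
            key: Freq(c, label_n[key[0]]) for key, c in sorted(per_group.items())
        },
        median_age_by_label={
            lab: float(np.median(a)) for lab, a in sorted(ages_by_label.items())
        },
        transfusion_dependent_count=td,
        pancytopenia_count=pancyto,
        complete_triad_count=triad_complete,
        bm_biopsy_counts=dict(sorted(bm_counts.items())),
    )


def specific_suspicion_count(results: Sequence[SuspicionResult]) -> int:
    """Patients whose primary label is one of the five specific syndromes."""
    return sum(1 for r in results if r.primary in _SPECIFIC)


_CONTINUOUS = {"age_years", "onset_age_years"}


def group_compare(
    cohort: Sequence[PatientRecord],
    results: Sequence[SuspicionResult],
    variable: str,
    kind: Literal["categorical", "continuous", "auto"] = "auto",
    config: RunConfig = RunConfig(),
    catalog: FeatureCatalog | None = None,
) -> GroupTestReport:
    """Compare a variable across primary-suspicion groups.

    Categorical variables get a chi-square test on the label × value
    contingency table; continuous variables a one-way ANOVA across
    labels. Cells with expected counts below 5 produce a warning.
    """
    from .hematology import hematology_profile

    cat = catalog if catalog is not None else load_catalog()
    pairs = _align(cohort, results)
    if kind == "auto":
        kind = "continuous" if variable in _CONTINUOUS else "categorical"

    def value_of(record: PatientRecord):
        if hasattr(record, variable):
            return getattr(record, variable)
        profile = hematology_profile(record, cat, config.thresholds)
        if hasattr(profile, variable):
            return getattr(profile, variable)
        raise CohortError(f"unknown variable {variable!r}")

    by_group: dict[str, list] = {}
    for record, res in pairs:
        v = value_of(record)
        if v is None:
            continue
        by_group.setdefault(_label(res), []).append(v)
    groups = sorted(by_group)
    if len(groups) < 2:
        raise CohortError("group comparison needs at least 2 groups")

    warnings: list[str] = []
    if kind == "continuous":
        fstat, p = stats.f_oneway(*(by_group[g] for g in groups))
        df = (len(groups) - 1, sum(len(v) for v in by_group.values()) - len(groups))
        return GroupTestReport(variable, kind, "one-way ANOVA", float(fstat), df,
                               float(p), groups, warnings)
    levels = sorted({v for vals in by_group.values() for v in vals}, key=str)
    table = np.array(
        [[sum(1 for v in by_group[g] if v == lev) for lev in levels] for g in groups]
    )
    table = table[:, table.sum(axis=0) > 0]
    chi2, p, df, expected = stats.chi2_contingency(table, correction=config.chi2_yates)
    if (expected < 5).any():
        warnings.append(
            f"{int((expected < 5).sum())} cell(s) with expected count < 5; "
            "chi-square approximation may be poor"
        )
    return GroupTestReport(variable, kind, "chi-square", float(chi2), float(df),
                           float(p), groups, warnings)


def chi2_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> float:
    """Pearson chi-square for a 2×2 table (convenience for checks)."""
    table = np.array([[a, b], [c, d]])
    chi2, _, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2)


def _fmt_freq(f: Freq) -> str:
    return f"{f.count} ({f.percent_truncated})"


def summary_tables(summary: CohortSummary) -> dict[str, "object"]:
    """Render the summary as pandas DataFrames mirroring the standard
    characteristics table and the per-group feature grid."""
    import pandas as pd

    general = pd.DataFrame(
        [
            *[("sex", k, v, math.nan) for k, v in summary.sex_counts.items()],
            *[
                ("onset_category", k, f.count, f.percent_truncated)
                for k, f in summary.onset_category_counts.items()
            ],
            *[("beacon", k, v, math.nan) for k, v in summary.beacon_counts.items()],
            *[("primary", k, v, math.nan) for k, v in summary.primary_label_counts.items()],
        ],
        columns=["block", "key", "count", "percent"],
    )
    features = pd.DataFrame(
        [
            (g, f.count, f.denominator, round(f.percent, 1), f.percent_truncated)
            for g, f in summary.feature_group_prevalence.items()
        ],
        columns=["group", "count", "denominator", "percent", "percent_truncated"],
    )
    per_label = pd.DataFrame(
        [
            (label, group, f.count, f.denominator, round(f.percent, 1))
            for (label, group), f in summary.per_group_feature_prevalence.items()
        ],
        columns=["label", "group", "count", "label_n", "percent"],
    )
    return {"general": general, "feature_groups": features, "per_label": per_label}
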