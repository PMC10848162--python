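"""CBC interpretation: per-lineage status, cytopenia class, onset,
transfusion dependency, persistent and cyclic neutropenia.

Severity bands are half-open ``[low, high)`` so that every ANC maps to
exactly one grade: ANC 1,000 is mild, 500 is moderate, anything below
500 severe. The cytopenia class is a pure function of how many lineages
(erythroid, myeloid, megakaryocytic) have *ever* been affected over the
series — the worst grade per lineage is kept, not a single-day snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .config import Thresholds
from .records import CBCMeasurement, PatientRecord, TransfusionEvent
from .terms import FeatureCatalog

NeutropeniaGrade = Literal["none", "mild", "moderate", "severe"]
AnemiaStatus = Literal["none", "normocytic", "macrocytic"]
OnsetCategory = Literal["le2", "gt2_le5", "gt5_lt18", "adult", "none"]

_GRADE_RANK = {"none": 0, "mild": 1, "moderate": 2, "severe": 3}
_ANEMIA_RANK = {"none": 0, "normocytic": 1, "macrocytic": 2}

LINEAGES = ("erythroid", "myeloid", "megakaryocytic")


@dataclass(frozen=True)
class LineageStatus:
    anemia: AnemiaStatus = "none"
    neutropenia: NeutropeniaGrade = "none"
    thrombocytopenia: Literal["absent", "present"] = "absent"
    reticulocytopenia: Literal["absent", "present", "unknown"] = "unknown"

    @property
    def affected_lineages(self) -> frozenset[str]:
        out = set()
        if self.anemia != "none":
            out.add("erythroid")
        if self.neutropenia != "none":
            out.add("myeloid")
        if self.thrombocytopenia == "present":
            out.add("megakaryocytic")
        return frozenset(out)


@dataclass(frozen=True)
class CytopeniaClass:
    value: Literal["none", "unilineage", "bilineage", "pancytopenia"]
    affected_lineages: frozenset[str]


@dataclass
class HematologyProfile:
    """Aggregate interpretation of a patient's full CBC history."""

    ever_status: LineageStatus
    worst_class: CytopeniaClass
    onset_age_years: Optional[float]
    onset_category: OnsetCategory
    transfusion_dependent: bool
    persistent_neutropenia: bool
    cyclic_neutropenia: bool
    macrocytic_anemia_with_reticulocytopenia: Optional[bool]
    flags: list[str] = field(default_factory=list)

    @property
    def any_cytopenia(self) -> bool:
        return self.worst_class.value != "none"


def grade_neutropenia(anc: float, ref: Thresholds = Thresholds()) -> NeutropeniaGrade:
    """Grade an absolute neutrophil count (cells/µL)."""
    if anc < 0:
        raise ValueError(f"ANC must be non-negative, got {anc}")
    if anc < ref.anc_severe:
        return "severe"
    if anc < ref.anc_moderate:
        return "moderate"
    if anc < ref.anc_mild:
        return "mild"
    return "none"


def classify_anemia(
    hb: float,
    mcv: Optional[float],
    age_years: float,
    sex: str = "unknown",
    ref: Thresholds = Thresholds(),
) -> tuple[AnemiaStatus, list[str]]:
    """Classify anemia at one measurement.

    Returns the status plus provenance flags; with the MCV unknown an
    anemic sample defaults to normocytic and is flagged.
    """
    if hb < 0:
        raise ValueError(f"Hb must be non-negative, got {hb}")
    if hb >= ref.hb_anemia:
        return "none", []
    if mcv is None:
        return "normocytic", ["mcv_unknown_default_normocytic"]
    if mcv > ref.mcv_uln(age_years):
        return "macrocytic", []
    return "normocytic", []


def lineage_status(
    m: CBCMeasurement, ref: Thresholds = Thresholds(), sex: str = "unknown"
) -> LineageStatus:
    anemia, _ = classify_anemia(m.hb, m.mcv, m.age_years, sex, ref)
    retic: Literal["absent", "present", "unknown"]
    if m.reticulocytes is None:
        retic = "unknown"
    else:
        retic = "present" if m.reticulocytes < ref.retic_abs_min else "absent"
    return LineageStatus(
        anemia=anemia,
        neutropenia=grade_neutropenia(m.anc, ref),
        thrombocytopenia="present" if m.platelets < ref.plt_threshold else "absent",
        reticulocytopenia=retic,
    )


def cytopenia_class(status: LineageStatus) -> CytopeniaClass:
    affected = status.affected_lineages
    value = {0: "none", 1: "unilineage", 2: "bilineage", 3: "pancytopenia"}[len(affected)]
    return CytopeniaClass(value=value, affected_lineages=affected)


def transfusion_dependent(
    events: list[TransfusionEvent], ref: Thresholds = Thresholds()
) -> bool:
    """True iff some inclusive 28-day window holds ≥ 2 RBC units.

    Non-RBC products are ignored; the window span is inclusive
    (day_j − day_i ≤ 28 counts).
    """
    days: list[int] = []
    for e in sorted(events, key=lambda e: e.age_days):
        if e.product == "RBC":
            days.extend([e.age_days] * e.units)
    k = ref.rbc_units_min
    for i in range(len(days) - k + 1):
        if days[i + k - 1] - days[i] <= ref.rbc_window_days:
            return True
    return False


def onset_category(age: Optional[float], ref: Thresholds = Thresholds()) -> OnsetCategory:
    if age is None:
        return "none"
    if age <= 2.0:
        return "le2"
    if age <= 5.0:
        return "gt2_le5"
    if age < ref.adult_onset_age:
        return "gt5_lt18"
    return "adult"


def onset(
    series: list[CBCMeasurement],
    features: list[tuple[str, Optional[float]]] = (),
    catalog: FeatureCatalog | None = None,
    ref: Thresholds = Thresholds(),
) -> tuple[Optional[float], OnsetCategory]:
    """Hematologic onset: age of the first CBC meeting any cytopenia
    criterion; with no (abnormal) series, the earliest dated hematologic
    feature annotation; None if never cytopenic."""
    for m in series:
        if cytopenia_class(lineage_status(m, ref)).value != "none":
            return m.age_years, onset_category(m.age_years, ref)
    if catalog is not None:
        dated = [
            a for t, a in features
            if a is not None and catalog.matches(t, "HP:0001871")
        ]
        if dated:
            first = min(dated)
            return first, onset_category(first, ref)
    return None, "none"


def persistent_neutropenia(
    series: list[CBCMeasurement], ref: Thresholds = Thresholds()
) -> bool:
    """Lifelong neutropenia: ANC below 1,500 in at least a fraction P of
    all measurements (default 0.9) and never at/above the recovery
    ceiling (default 2,500) — tolerant of occasional post-treatment
    normal values."""
    if not series:
        return False
    ancs = [m.anc for m in series]
    if any(a >= ref.persistence_ceiling for a in ancs):
        return False
    frac = sum(a < ref.anc_mild for a in ancs) / len(ancs)
    return frac >= ref.persistence_fraction


def cyclic_pattern(series: list[CBCMeasurement], ref: Thresholds = Thresholds()) -> bool:
    """Cyclic neutropenia: the ANC series crosses the neutropenia
    threshold downward at least twice, with at least one nadir below
    500. Requires ≥ 4 measurements."""
    if len(series) < 4:
        return False
    ancs = [m.anc for m in series]
    down = sum(
        1 for a, b in zip(ancs, ancs[1:]) if a >= ref.anc_mild and b < ref.anc_mild
    )
    return down >= ref.cyclic_crossings_min and min(ancs) < ref.cyclic_nadir


def _worst(statuses: list[LineageStatus]) -> LineageStatus:
    if not statuses:
        return LineageStatus()
    retic = "unknown"
    if any(s.reticulocytopenia == "present" for s in statuses):
        retic = "present"
    elif all(s.reticulocytopenia == "absent" for s in statuses):
        retic = "absent"
    return LineageStatus(
        anemia=max((s.anemia for s in statuses), key=_ANEMIA_RANK.__getitem__),
        neutropenia=max((s.neutropenia for s in statuses), key=_GRADE_RANK.__getitem__),
        thrombocytopenia=(
            "present" if any(s.thrombocytopenia == "present" for s in statuses) else "absent"
        ),
        reticulocytopenia=retic,
    )


def hematology_profile(
    record: PatientRecord,
    catalog: FeatureCatalog | None = None,
    ref: Thresholds = Thresholds(),
) -> HematologyProfile:
    """Deterministic aggregate of the per-measurement interpretations."""
    statuses = [lineage_status(m, ref, record.sex) for m in record.cbc_series]
    ever = _worst(statuses)
    flags: list[str] = []

    # tri-state: True if any single measurement is macrocytic-anemic with
    # reticulocytes below the cutoff; unknown (None) if the only
    # macrocytic-anemic samples lack a reticulocyte count or there is no
    # series at all; otherwise False.
    macro_retic: Optional[bool]
    qualifying = False
    macro_unmeasured = False
    for m in record.cbc_series:
        status, f = classify_anemia(m.hb, m.mcv, m.age_years, record.sex, ref)
        flags.extend(f)
        if status == "macrocytic":
            if m.reticulocytes is None:
                macro_unmeasured = True
            elif m.reticulocytes < ref.retic_abs_min:
                qualifying = True
    if qualifying:
        macro_retic = True
    elif macro_unmeasured:
        macro_retic = None
        flags.append("macrocytic_anemia_but_reticulocytes_unknown")
    elif record.cbc_series:
        macro_retic = False
    else:
        macro_retic = None

    onset_age, category = onset(
        record.cbc_series,
        [(f.term_id, f.onset_age_years) for f in record.features],
        catalog,
        ref,
    )
    if len(record.cbc_series) < 4:
        flags.append("cyclic_assessment_underpowered")
    return HematologyProfile(
        ever_status=ever,
        worst_class=cytopenia_class(ever),
        onset_age_years=onset_age,
        onset_category=category,
        transfusion_dependent=transfusion_dependent(record.transfusions, ref),
        persistent_neutropenia=persistent_neutropenia(record.cbc_series, ref),
        cyclic_neutropenia=cyclic_pattern(record.cbc_series, ref),
        macrocytic_anemia_with_reticulocytopenia=macro_retic,
        flags=flags,
    )
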