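"""Synthetic cohorts: the deterministic 48-patient reference cohort and
a seeded random cohort simulator.

``build_reference_fixture`` expands the frozen per-patient table into
full records — no randomness anywhere, so the fixture is bit-stable
across runs and platforms. ``simulate_cohort`` draws arbitrarily many
patients per syndrome archetype with published feature prevalences as
sampling probabilities; each patient gets an independent substream of a
named, seedable PRNG (numpy PCG64 via ``SeedSequence.spawn``), so
cohorts are reproducible and insensitive to patient order.

Simulated records carry both the *intended* archetype and the
*expected* triage label: a record whose sampled features fall below its
archetype's minimal rule threshold is expected to fall through to
undefined IBMFS, and the generator marks it as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from . import _fixture_data as _fx
from .records import (
    CBCMeasurement,
    FamilyHistory,
    LabPanel,
    MalignancyEvent,
    PatientRecord,
    PrenatalHistory,
    TransfusionEvent,
)

Label = Literal["DC", "SDS", "DBA", "TAR", "SCN", "undefined_IBMFS"]


# ---------------------------------------------------------------------------
# deterministic reference fixture


def _expand_series(start: Optional[float], age: float, pattern: str) -> list[CBCMeasurement]:
    rows = _fx.CBC_PATTERNS[pattern]
    if start is None:
        anchor, span = age, 0.0
    else:
        anchor, span = start, age - start
    out = []
    for pos, hb, mcv, anc, plt, retic in rows:
        out.append(CBCMeasurement(
            age_years=round(anchor + pos * span, 4),
            hb=hb, mcv=mcv, anc=anc, platelets=plt, reticulocytes=retic,
        ))
    return out


def _expand_transfusions(start: Optional[float], flags: list[str]) -> list[TransfusionEvent]:
    base = int((start or 0.5) * 365)
    if "td" in flags:
        days = [base, base + 20, base + 60]
    elif "tx_spread" in flags:
        days = [base, base + 29]
    elif "tx_single" in flags:
        days = [base]
    else:
        return []
    return [TransfusionEvent(age_days=d, product="RBC", units=1) for d in days]


def build_reference_fixture() -> tuple[list[PatientRecord], dict[str, Label]]:
    """The 48-patient reference cohort and its intended labels."""
    records: list[PatientRecord] = []
    intended: dict[str, Label] = {}
    for num, label, sex, age, start, pattern, features, flags in _fx.PATIENTS:
        pid = f"P{num:02d}"
        fam = f"FAM{int(next((f.split(':')[1] for f in flags if f.startswith('sib:')), num)):02d}"
        bm = [f.split(":")[1] for f in flags if f.startswith("bm:")] or ["not_done"]
        malignancy = []
        for f in flags:
            if f.startswith("mal:"):
                mtype, onset_age = f[4:].split("@")
                malignancy.append(MalignancyEvent(type=mtype, onset_age_years=float(onset_age)))
        record = PatientRecord(
            patient_id=pid,
            family_id=fam,
            sex=sex,
            age_years=age,
            features=[{"term_id": t} for t in features],
            cbc_series=_expand_series(start, age, pattern),
            transfusions=_expand_transfusions(start, flags),
            labs=LabPanel(
                deb_test="negative",
                ffqt="positive" if "ffqt" in flags else "not_done",
                bm_biopsy=bm,
                viral_serology_positive=False,
                nutritional_deficiency=False,
                drug_radiation_exposure=False,
                pnh_clone=False,
            ),
            family=FamilyHistory(
                consanguinity_degree=3 if "consang" in flags else None,
                settlement_population=3000 if "endogamy" in flags else None,
                shared_surname=True if "surname" in flags else None,
                hematological_disorder_in_family=True if "famheme" in flags else None,
            ),
            prenatal=PrenatalHistory(
                fgr=True if "fgr" in flags else None,
                sga=True if "sga" in flags else None,
            ),
            personal_malignancy=malignancy,
        )
        records.append(record)
        intended[pid] = label  # type: ignore[assignment]
    return records, intended


# ---------------------------------------------------------------------------
# seeded simulator


@dataclass(frozen=True)
class CBCTrajectory:
    """Per-archetype CBC generator parameters: lineage baselines with
    measurement noise, sampled onset-age window, qualitative shape."""

    kind: Literal["dba", "sds", "dc", "tar", "scn", "undefined"]
    onset_window: tuple[float, float]
    n_measurements: int = 3


@dataclass(frozen=True)
class ArchetypeParams:
    label: Label
    n: int
    feature_prevalence: dict[str, float]
    cbc_trajectory: CBCTrajectory
    lab_settings: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for term, p in self.feature_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {term} outside [0,1]: {p}")


def default_params(scale: int = 1) -> list[ArchetypeParams]:
    """Archetype parameters encoding the published cohort: group sizes
    15/9/7/2/2/13 and the per-group feature prevalences of the clinical
    characteristics grid (e.g. growth restriction 8/9 in SDS and 8/15 in
    DBA, leukoplakia 4/7 and nail dysplasia 5/7 in DC)."""
    return [
        ArchetypeParams(
            label="DBA", n=15 * scale,
            feature_prevalence={
                "HP:0000414": 1.0,            # >=1 minor craniofacial feature in all
                "HP:0004322": 8 / 15,
                "HP:0000957": 10 / 15,
                "HP:0012758": 12 / 15,
            },
            cbc_trajectory=CBCTrajectory("dba", (0.2, 6.0)),
        ),
        ArchetypeParams(
            label="SDS", n=9 * scale,
            feature_prevalence={
                "HP:0001738": 6 / 9,
                "HP:0002024": 5 / 9,
                "HP:0004322": 8 / 9,
                "HP:0002240": 2 / 9,
                "HP:0012758": 5 / 9,
                "HP:0000286": 7 / 9,
                "HP:0007441": 6 / 9,
            },
            cbc_trajectory=CBCTrajectory("sds", (0.3, 4.0)),
            lab_settings={"ffqt_positive": 4 / 9},
        ),
        ArchetypeParams(
            label="DC", n=7 * scale,
            feature_prevalence={
                "HP:0002745": 4 / 7,
                "HP:0002164": 5 / 7,
                "HP:0007427": 1.0,
                "HP:0004322": 2 / 7,
                "HP:0012758": 5 / 7,
                "HP:0000276": 5 / 7,
            },
            cbc_trajectory=CBCTrajectory("dc", (1.0, 12.0)),
        ),
        ArchetypeParams(
            label="TAR", n=2 * scale,
            feature_prevalence={
                "HP:0003974": 1.0,
                "HP:0009601": 0.5,
                "HP:0012758": 0.5,
                "HP:0000414": 0.5,
            },
            cbc_trajectory=CBCTrajectory("tar", (0.05, 0.5), n_measurements=2),
        ),
        ArchetypeParams(
            label="SCN", n=2 * scale,
            feature_prevalence={
                "HP:0012758": 1.0,
                "HP:0001627": 1.0,
                "HP:0004322": 0.5,
                "HP:0000119": 0.5,
                "HP:0000308": 1.0,
            },
            cbc_trajectory=CBCTrajectory("scn", (0.1, 1.0), n_measurements=6),
        ),
        ArchetypeParams(
            label="undefined_IBMFS", n=13 * scale,
            feature_prevalence={
                "HP:0000414": 10 / 13,
                "HP:0001510": 2 / 13,
            },
            cbc_trajectory=CBCTrajectory("undefined", (0.5, 16.0)),
        ),
    ]


@dataclass
class SimulatedPatient:
    record: PatientRecord
    intended_label: Label
    #: label the triage rules should assign; undefined_IBMFS when the
    #: sampled features fall below the archetype's minimal rule
    expected_label: Label


def _noisy(rng: np.random.Generator, mean: float, sd: float, low: float = 0.0) -> float:
    return float(max(low, rng.normal(mean, sd)))


def _simulate_cbc(rng: np.random.Generator, traj: CBCTrajectory, onset: float) -> list[CBCMeasurement]:
    ages = onset + np.sort(rng.uniform(0.0, 2.0, traj.n_measurements - 1))
    ages = np.round(np.concatenate([[onset], ages + 0.05]), 4)
    # keep ages strictly increasing after rounding
    ages = np.maximum.accumulate(ages + np.arange(len(ages)) * 1e-4)
    rows = []
    for i, a in enumerate(ages):
        if traj.kind == "dba":
            hb, mcv = _noisy(rng, 7.4, 0.5), _noisy(rng, 109, 2)
            anc, plt, retic = _noisy(rng, 3000, 300), _noisy(rng, 250_000, 20_000), _noisy(rng, 8, 3)
        elif traj.kind == "sds":
            hb, mcv = _noisy(rng, 9.5, 0.5), _noisy(rng, 86, 2)
            anc = _noisy(rng, 2800, 200) if i == len(ages) - 1 else _noisy(rng, 420, 80)
            plt, retic = _noisy(rng, 120_000, 15_000), _noisy(rng, 30, 4)
        elif traj.kind == "dc":
            hb, mcv = _noisy(rng, 8.6, 0.5), _noisy(rng, 87, 2)
            anc = _noisy(rng, 2700, 150) if i == len(ages) - 1 else _noisy(rng, 1000, 150)
            plt, retic = _noisy(rng, 60_000, 10_000), _noisy(rng, 28, 3)
        elif traj.kind == "tar":
            hb, mcv = _noisy(rng, 11.5, 0.4, low=10.6), _noisy(rng, 86, 2)
            anc, plt, retic = _noisy(rng, 3200, 200, low=2600), _noisy(rng, 45_000, 8_000), _noisy(rng, 45, 5)
        elif traj.kind == "scn":
            hb, mcv = _noisy(rng, 12.4, 0.3, low=11.0), _noisy(rng, 85, 1)
            anc = _noisy(rng, 1800, 80, low=1600) if i % 2 == 0 else _noisy(rng, 280, 60)
            plt, retic = _noisy(rng, 230_000, 15_000), _noisy(rng, 49, 3)
        else:  # undefined: normocytic multilineage involvement, recovery
            hb, mcv = _noisy(rng, 8.7, 0.4), _noisy(rng, 87, 1.5)
            anc = _noisy(rng, 2700, 120, low=2500) if i == len(ages) - 1 else _noisy(rng, 1050, 120)
            plt, retic = _noisy(rng, 60_000, 12_000), _noisy(rng, 29, 3)
        rows.append(CBCMeasurement(
            age_years=round(float(a), 4), hb=round(hb, 1), mcv=round(mcv, 1),
            anc=round(anc), platelets=round(plt), reticulocytes=round(retic, 1),
        ))
    return rows


_SCN_ASSOC = ("HP:0004322", "HP:0001627", "HP:0000119")
_SDS_ASSOC = ("HP:0001738", "HP:0002024", "HP:0004322", "HP:0005871",
              "HP:0045027", "HP:0001627", "HP:0000598", "HP:0002240")
_DC_TRIAD = ("HP:0002745", "HP:0002164", "HP:0007427")


def _expected_label(label: Label, terms: set[str], ffqt_pos: bool) -> Label:
    """Generator-side minimal-rule check. All hematologic archetypes
    produce a genuine cytopenia by construction, so only the sampled
    phenotype can push a record below its rule threshold."""
    if label == "DC":
        return "DC" if any(t in terms for t in _DC_TRIAD) else "undefined_IBMFS"
    if label == "SDS":
        n = len({t for t in terms if t in _SDS_ASSOC} | ({"HP:0001738"} if ffqt_pos else set()))
        return "SDS" if (n >= 3 or ffqt_pos) else "undefined_IBMFS"
    if label == "SCN":
        n = sum(t in terms for t in _SCN_ASSOC)
        return "SCN" if n >= 2 else "undefined_IBMFS"
    if label == "TAR":
        return "TAR" if "HP:0003974" in terms else "undefined_IBMFS"
    return label  # DBA trigger is in the CBC; undefined stays undefined


#: stable per-archetype stream keys so each simulated patient's PRNG
#: substream depends only on (seed, label, index), not cohort layout
_LABEL_CODE = {"DBA": 0, "SDS": 1, "DC": 2, "TAR": 3, "SCN": 4, "undefined_IBMFS": 5}


def simulate_cohort(
    params: list[ArchetypeParams], seed: int
) -> list[SimulatedPatient]:
    """Draw a cohort; same seed and params give an identical cohort."""
    out: list[SimulatedPatient] = []
    for arche in params:
        for j in range(arche.n):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, _LABEL_CODE[arche.label], j])
            )
            terms = {
                t for t, p in sorted(arche.feature_prevalence.items())
                if rng.random() < p
            }
            ffqt_pos = rng.random() < arche.lab_settings.get("ffqt_positive", 0.0)
            lo, hi = arche.cbc_trajectory.onset_window
            onset_age = float(rng.uniform(lo, hi))
            series = _simulate_cbc(rng, arche.cbc_trajectory, onset_age)
            age = round(series[-1].age_years + float(rng.uniform(0.5, 3.0)), 2)
            pid = f"SIM-{arche.label}-{j:04d}"
            record = PatientRecord(
                patient_id=pid,
                family_id=pid,
                sex="male" if rng.random() < 29 / 48 else "female",
                age_years=age,
                features=[{"term_id": t} for t in sorted(terms)],
                cbc_series=series,
                labs=LabPanel(
                    deb_test="negative",
                    ffqt="positive" if ffqt_pos else "not_done",
                    viral_serology_positive=False,
                    nutritional_deficiency=False,
                    drug_radiation_exposure=False,
                    pnh_clone=False,
                ),
            )
            out.append(SimulatedPatient(
                record=record,
                intended_label=arche.label,
                expected_label=_expected_label(arche.label, terms, ffqt_pos),
            ))
    return out
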