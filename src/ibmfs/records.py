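"""Patient records: validated domain types and JSON/NDJSON/CSV I/O.

A patient record is one JSON object per file. History and laboratory
fields are tri-state: ``true`` / ``false`` / absent-or-null meaning
*unknown*. An absent key never means negative — the triage rules must
distinguish a test that was not done from a negative result.

Units are fixed (Hb g/dL; ANC and platelets cells/µL; reticulocytes
absolute ×10⁹/L). A record that declares different units is rejected
rather than converted silently.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .terms import CatalogError, FeatureCatalog, load_catalog, normalize_term_id


class RecordError(ValueError):
    """Raised when a patient record fails validation."""


CANONICAL_UNITS = {
    "hb": "g/dL",
    "anc": "cells/uL",
    "platelets": "cells/uL",
    "reticulocytes": "1e9/L",
}

CBC_CSV_COLUMNS = [
    "age_years", "hb", "mcv", "anc", "platelets", "wbc", "retic_abs", "hbf_percent",
]


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class FeatureAssertion(_Base):
    term_id: str
    onset_age_years: Optional[float] = Field(default=None, ge=0, lt=130)

    @field_validator("term_id")
    @classmethod
    def _norm(cls, v: str) -> str:
        return normalize_term_id(v)


class CBCMeasurement(_Base):
    age_years: float = Field(ge=0, lt=130)
    hb: float = Field(ge=0)
    mcv: Optional[float] = Field(default=None, ge=0)
    anc: float = Field(ge=0)
    platelets: float = Field(ge=0)
    wbc: Optional[float] = Field(default=None, ge=0)
    reticulocytes: Optional[float] = Field(default=None, ge=0)
    hbf_percent: Optional[float] = Field(default=None, ge=0, le=100)


class TransfusionEvent(_Base):
    age_days: int = Field(ge=0)
    product: Literal["RBC", "platelet", "other"]
    units: int = Field(ge=1)


BiopsyFinding = Literal[
    "hypocellular", "normal", "mds", "aml", "erythroid_paucity", "not_done"
]


class LabPanel(_Base):
    deb_test: Literal["positive", "negative", "not_done"] = "not_done"
    ffqt: Literal["positive", "negative", "not_done"] = "not_done"
    bm_biopsy: list[BiopsyFinding] = Field(default_factory=lambda: ["not_done"])
    viral_serology_positive: Optional[bool] = None
    nutritional_deficiency: Optional[bool] = None
    drug_radiation_exposure: Optional[bool] = None
    pnh_clone: Optional[bool] = None
    eada_elevated: Optional[bool] = None


class FamilyHistory(_Base):
    consanguinity_degree: Optional[int] = Field(default=None, ge=1)
    settlement_population: Optional[int] = Field(default=None, ge=1)
    shared_surname: Optional[bool] = None
    hematological_disorder_in_family: Optional[bool] = None
    malignancy_in_family: Optional[bool] = None


class PrenatalHistory(_Base):
    fgr: Optional[bool] = None
    sga: Optional[bool] = None


class MalignancyEvent(_Base):
    type: Literal["MDS", "AML", "ALL", "solid_tumor"]
    onset_age_years: Optional[float] = Field(default=None, ge=0, lt=130)


class PatientRecord(_Base):
    patient_id: str = Field(min_length=1)
    family_id: Optional[str] = None
    sex: Literal["male", "female", "unknown"] = "unknown"
    age_years: float = Field(ge=0, lt=130)
    features: list[FeatureAssertion] = Field(default_factory=list)
    cbc_series: list[CBCMeasurement] = Field(default_factory=list)
    transfusions: list[TransfusionEvent] = Field(default_factory=list)
    labs: LabPanel = Field(default_factory=LabPanel)
    family: FamilyHistory = Field(default_factory=FamilyHistory)
    prenatal: PrenatalHistory = Field(default_factory=PrenatalHistory)
    personal_malignancy: list[MalignancyEvent] = Field(default_factory=list)

    @model_validator(mode="after")
    def _cbc_sorted(self) -> "PatientRecord":
        ages = [m.age_years for m in self.cbc_series]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("cbc_series not sorted strictly by age_years")
        return self

    @property
    def feature_ids(self) -> list[str]:
        return [f.term_id for f in self.features]


def _check_units(declared: dict | None) -> None:
    if not declared:
        return
    for key, unit in declared.items():
        want = CANONICAL_UNITS.get(key)
        if want is None:
            raise RecordError(f"units declared for unknown quantity {key!r}")
        if unit != want:
            raise RecordError(
                f"record declares {key} in {unit!r}; expected {want!r} "
                "(unit conversion is not performed)"
            )


def _cbc_from_csv(path: Path) -> list[dict]:
    df = pd.read_csv(path)
    if list(df.columns) != CBC_CSV_COLUMNS:
        raise RecordError(
            f"CBC sidecar {path.name}: header must be {','.join(CBC_CSV_COLUMNS)}"
        )
    rows = []
    rename = {"retic_abs": "reticulocytes"}
    for rec in df.to_dict(orient="records"):
        row = {}
        for k, v in rec.items():
            if isinstance(v, float) and math.isnan(v):
                continue
            row[rename.get(k, k)] = v
        rows.append(row)
    return rows


def read_patient_record(
    source: str | Path | dict,
    catalog: FeatureCatalog | None = None,
) -> PatientRecord:
    """Read and validate one patient record.

    *source* may be a path to a JSON file, a JSON string, or an
    already-parsed mapping. HPO ids are normalized to the zero-padded
    form; term ids that do not resolve in the catalog are an error
    listing the nearest catalog labels.
    """
    base_dir = Path(".")
    if isinstance(source, dict):
        data = dict(source)
    else:
        text: str
        p = Path(str(source))
        if isinstance(source, Path) or (p.suffix == ".json" and p.exists()):
            text = p.read_text()
            base_dir = p.parent
        else:
            text = str(source)
        try:
            data = json.loads(text)
        except json.JSONDecodeError as e:
            raise RecordError(f"invalid JSON: {e}") from e
    if not isinstance(data, dict):
        raise RecordError("patient record must be a JSON object")
    if not data.get("patient_id"):
        raise RecordError("missing patient_id")

    _check_units(data.pop("units", None))
    sidecar = data.pop("cbc_csv", None)
    if sidecar is not None:
        if data.get("cbc_series"):
            raise RecordError("record has both cbc_series and cbc_csv")
        data["cbc_series"] = _cbc_from_csv(base_dir / sidecar)

    try:
        record = PatientRecord.model_validate(data)
    except (ValueError, CatalogError) as e:
        raise RecordError(f"record {data.get('patient_id')!r}: {e}") from e

    cat = catalog if catalog is not None else load_catalog()
    for feat in record.features:
        if feat.term_id not in cat.terms:
            near = "; ".join(cat.nearest_labels(feat.term_id))
            raise RecordError(
                f"record {record.patient_id!r}: unknown term {feat.term_id} "
                f"(nearest catalog entries: {near})"
            )
    return record


def write_patient_record(record: PatientRecord, sink: str | Path) -> None:
    """Write a record as JSON; unknown tri-state fields are omitted so
    that the round trip preserves unknown-ness."""
    payload = record.model_dump(mode="json", exclude_none=True)
    Path(sink).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def record_to_json(record: PatientRecord) -> str:
    return json.dumps(record.model_dump(mode="json", exclude_none=True), sort_keys=True)


def read_cohort(
    source: str | Path,
    catalog: FeatureCatalog | None = None,
) -> list[PatientRecord]:
    """Read a cohort: a directory of ``*.json`` files or one NDJSON file.

    Per-file errors are aggregated into a single RecordError; duplicate
    patient ids are an error.
    """
    path = Path(source)
    cat = catalog if catalog is not None else load_catalog()
    records: list[PatientRecord] = []
    errors: list[str] = []
    if path.is_dir():
        # files starting with "_" are cohort metadata (e.g. a label
        # manifest), not patient records
        for f in sorted(path.glob("[!_]*.json")):
            try:
                records.append(read_patient_record(f, cat))
            except RecordError as e:
                errors.append(f"{f.name}: {e}")
    else:
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                records.append(read_patient_record(json.loads(line), cat))
            except (RecordError, json.JSONDecodeError) as e:
                errors.append(f"line {i}: {e}")
    seen: dict[str, int] = {}
    for r in records:
        seen[r.patient_id] = seen.get(r.patient_id, 0) + 1
    dupes = sorted(pid for pid, n in seen.items() if n > 1)
    if dupes:
        errors.append(f"duplicate patient_id(s): {dupes}")
    if errors:
        raise RecordError("cohort read failed:\n  " + "\n  ".join(errors))
    return records
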