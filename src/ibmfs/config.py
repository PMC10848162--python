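"""Run configuration: interpretation thresholds and engine options.

Defaults encode the triage conventions: anemia below Hb 10.5 g/dL,
neutropenia below ANC 1,500/µL (severe < 500, moderate 500–1,000, mild
1,000–1,500, half-open bands), thrombocytopenia below 150,000/µL,
reticulocytopenia below an absolute 20 ×10⁹/L, endogamy below a
settlement of 5,000 inhabitants, and transfusion dependency as ≥ 2 RBC
units within any inclusive 28-day span. The macrocytosis cutoff and the
neutropenia-persistence fraction are not dictated by the source
criteria and are exposed here (flat 100 fL; P = 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys or malformed threshold configuration."""


@dataclass(frozen=True)
class MCVBand:
    """Upper limit of normal MCV (fL) for ages below ``max_age``."""

    max_age: float
    uln: float


@dataclass(frozen=True)
class Thresholds:
    hb_anemia: float = 10.5                 # g/dL
    anc_severe: float = 500.0               # cells/uL, half-open bands
    anc_moderate: float = 1000.0
    anc_mild: float = 1500.0
    plt_threshold: float = 150_000.0        # cells/uL
    retic_abs_min: float = 20.0             # 1e9/L
    mcv_table: tuple[MCVBand, ...] = (MCVBand(max_age=130.0, uln=100.0),)
    persistence_fraction: float = 0.9
    persistence_ceiling: float = 2500.0     # any ANC at/above this breaks persistence
    cyclic_crossings_min: int = 2
    cyclic_nadir: float = 500.0
    rbc_window_days: int = 28
    rbc_units_min: int = 2
    settlement_endogamy_max: int = 5000
    adult_onset_age: float = 18.0

    def mcv_uln(self, age_years: float) -> float:
        for band in self.mcv_table:
            if age_years < band.max_age:
                return band.uln
        return self.mcv_table[-1].uln


#: precedence when several syndrome rules fire: structural hallmark
#: (TAR) > lifetime neutropenia (SCN) > mucocutaneous (DC) >
#: multi-system (SDS) > erythroid (DBA)
DEFAULT_PRECEDENCE = ("TAR", "SCN", "DC", "SDS", "DBA")


@dataclass(frozen=True)
class RunConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
    chi2_yates: bool = False
    schema_version: int = 1


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; unknown keys are rejected, absent keys keep
    their defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    known_top = {"thresholds", "precedence", "chi2_yates"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    thr = Thresholds()
    tblock = raw.get("thresholds") or {}
    valid = {f.name for f in fields(Thresholds)}
    bad = set(tblock) - valid
    if bad:
        raise ConfigError(f"unknown threshold keys: {sorted(bad)}")
    if "mcv_table" in tblock:
        bands = tuple(
            MCVBand(max_age=float(b["max_age"]), uln=float(b["uln"]))
            for b in tblock["mcv_table"]
        )
        if list(bands) != sorted(bands, key=lambda b: b.max_age):
            raise ConfigError("mcv_table bands must be sorted by max_age")
        tblock = {**tblock, "mcv_table": bands}
    thr = replace(thr, **tblock)

    prec = tuple(raw.get("precedence", DEFAULT_PRECEDENCE))
    if sorted(prec) != sorted(DEFAULT_PRECEDENCE):
        raise ConfigError(
            f"precedence must be a permutation of {DEFAULT_PRECEDENCE}, got {prec}"
        )
    return RunConfig(
        thresholds=thr,
        precedence=prec,
        chi2_yates=bool(raw.get("chi2_yates", False)),
    )
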