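"""Feature catalog: a bundled mini-HPO term table with descendant matching.

Phenotype matching throughout the package is *by exact term or
descendant within this catalog*: a patient annotated with
neurodevelopmental delay (HP:0012758) counts toward the
neurological-abnormality root (HP:0000707). The catalog only encodes the
parent links the triage rules need; it does not attempt to mirror the
full ontology.
"""

from __future__ import annotations

import difflib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import _catalog_data as _data

logger = logging.getLogger(__name__)

_HPO_CANONICAL = re.compile(r"^HP:\d{7}$")
_HPO_LOOSE = re.compile(r"^HP:?\s*([\d,]+)$")


class CatalogError(ValueError):
    """Raised for malformed catalog configuration or unresolvable terms."""


def normalize_term_id(raw: str) -> str:
    """Normalize an HPO identifier to the canonical zero-padded form.

    Truncated or comma-grouped codes as sometimes printed in clinical
    text ("HP:001972", "HP:001,972") are zero-padded to seven digits
    with a logged warning. Anything else is rejected.
    """
    raw = raw.strip()
    if _HPO_CANONICAL.match(raw):
        return raw
    m = _HPO_LOOSE.match(raw)
    if m:
        digits = m.group(1).replace(",", "")
        if digits.isdigit() and 0 < len(digits) <= 7:
            fixed = f"HP:{int(digits):07d}"
            logger.warning("normalized malformed HPO id %r -> %s", raw, fixed)
            return fixed
    raise CatalogError(f"malformed HPO term id: {raw!r}")


@dataclass(frozen=True)
class PhenoTerm:
    """One catalog term: identifier, label, and catalog parent links."""

    term_id: str
    label: str
    parent_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not _HPO_CANONICAL.match(self.term_id):
            raise CatalogError(f"term id not in HP:NNNNNNN form: {self.term_id!r}")


@dataclass
class FeatureCatalog:
    """Term table plus named rule groups, with ancestor-closure matching."""

    terms: dict[str, PhenoTerm]
    groups: dict[str, frozenset[str]]
    organ_systems: dict[str, str] = field(default_factory=dict)
    equivalents: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.groups.items():
            missing = sorted(m for m in members if m not in self.terms)
            if missing:
                raise CatalogError(f"group {name!r} references unknown terms: {missing}")
        self._ancestors: dict[str, frozenset[str]] = {}
        for tid in self.terms:
            self._ancestors[tid] = self._close(tid, ())

    def _close(self, tid: str, stack: tuple[str, ...]) -> frozenset[str]:
        if tid in stack:
            raise CatalogError(f"parent links form a cycle at {tid}")
        cached = self._ancestors.get(tid)
        if cached is not None:
            return cached
        out: set[str] = set()
        for p in self.terms[tid].parent_ids:
            if p not in self.terms:
                raise CatalogError(f"term {tid} has unknown parent {p}")
            out.add(p)
            out.update(self._close(p, stack + (tid,)))
        return frozenset(out)

    # -- matching ----------------------------------------------------------

    def ancestors(self, term_id: str) -> frozenset[str]:
        return self._ancestors[term_id]

    def matches(self, asserted: str, target: str) -> bool:
        """True iff *asserted* is *target*, a catalog descendant of it,
        or a declared equivalent (triad nail-element case)."""
        if asserted not in self.terms:
            return False
        if asserted == target or target in self._ancestors[asserted]:
            return True
        return asserted in self.equivalents.get(target, ())

    def matches_group(self, asserted: str, group: str) -> bool:
        return any(self.matches(asserted, t) for t in self.groups[group])

    def group_hits(self, term_ids: list[str] | set[str], group: str) -> set[str]:
        """Group members satisfied by any of the asserted terms."""
        return {
            t for t in self.groups[group]
            if any(self.matches(a, t) for a in term_ids)
        }

    def organ_systems_hit(self, term_ids: list[str] | set[str]) -> set[str]:
        """Distinct non-hematological organ systems covered by the terms."""
        hit = set()
        for name, root in self.organ_systems.items():
            if any(self.matches(a, root) for a in term_ids):
                hit.add(name)
        return hit

    def label_of(self, term_id: str) -> str:
        return self.terms[term_id].label

    def nearest_labels(self, unknown_id: str, n: int = 3) -> list[str]:
        pool = [f"{t.term_id} ({t.label})" for t in self.terms.values()]
        return difflib.get_close_matches(unknown_id, pool, n=n, cutoff=0.0)


def _builtin() -> FeatureCatalog:
    terms = {
        tid: PhenoTerm(tid, label, parents)
        for tid, (label, parents) in _data.TERMS.items()
    }
    return FeatureCatalog(
        terms=terms,
        groups=dict(_data.GROUPS),
        organ_systems=dict(_data.ORGAN_SYSTEMS),
        equivalents=dict(_data.GROUP_EQUIVALENTS),
    )


def load_catalog(config_path: str | Path | None = None) -> FeatureCatalog:
    """Return the bundled catalog, optionally extended by a YAML config.

    The config may add terms (``terms: {HP:XXXXXXX: {label, parents}}``)
    and add members to groups (``groups: {name: [ids]}``); it may not
    remove terms from the rule-required groups.
    """
    cat = _builtin()
    if config_path is None:
        return cat
    raw = yaml.safe_load(Path(config_path).read_text()) or {}
    if not isinstance(raw, dict):
        raise CatalogError("catalog config must be a mapping")
    for tid, spec in (raw.get("terms") or {}).items():
        tid = normalize_term_id(tid)
        parents = tuple(normalize_term_id(p) for p in spec.get("parents", []))
        cat.terms[tid] = PhenoTerm(tid, str(spec.get("label", tid)), parents)
    new_groups = dict(cat.groups)
    for name, members in (raw.get("groups") or {}).items():
        members = frozenset(normalize_term_id(m) for m in members)
        if name in _data.PROTECTED_GROUPS:
            lost = cat.groups[name] - members
            if lost:
                raise CatalogError(
                    f"group {name!r} is rule-required; config may not remove {sorted(lost)}"
                )
        new_groups[name] = members
    return FeatureCatalog(
        terms=cat.terms,
        groups=new_groups,
        organ_systems=cat.organ_systems,
        equivalents=cat.equivalents,
    )
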