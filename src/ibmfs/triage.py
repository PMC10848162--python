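"""The decision algorithm: eligibility gate, acquired-cause exclusion,
hereditary-suspicion beacons, six per-syndrome rules, and precedence.

Flow
----
1. *Eligibility*: a hematologic presentation (any cytopenia or marrow
   failure) or ≥ 2 non-hematological manifestations in distinct organ
   systems, together with at least one of positive family history, a
   physical abnormality, or hematologic onset before 18 years.
2. *Exclusion*: a positive DEB chromosomal-breakage test is a confirmed
   Fanconi anemia diagnosis (terminal); a positive acquired-cause panel
   (nutritional deficiency, viral serology, drug/radiation exposure,
   PNH clone) excludes the patient from hereditary triage. Unknown
   results never exclude — they are flagged as incomplete work-up.
3. *Rules*: each syndrome rule reports whether it fired, the matched and
   missing criteria, and a score over its specific feature set.
4. *Precedence*: when several rules fire, structural hallmark (TAR) >
   lifetime neutropenia (SCN) > mucocutaneous (DC) > multi-system (SDS)
   > erythroid (DBA). The FA pattern is a referral flag ("order DEB
   test"), primary only when it fires exclusively with the DEB test not
   done. An eligible, non-excluded record firing nothing falls back to
   undefined IBMFS.

Phenotype-only pathways exist for exactly the syndromes with a
non-hematologic hallmark: DC (complete mucocutaneous triad), SDS
(positive fecal-fat test), and FA (≥ 3 VACTERL-H/PHENOS features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .config import RunConfig
from .hematology import HematologyProfile, hematology_profile
from .records import PatientRecord
from .terms import FeatureCatalog, load_catalog

Syndrome = Literal["FA", "DC", "SDS", "DBA", "TAR", "SCN"]
Primary = Literal[
    "DC", "SDS", "DBA", "TAR", "SCN", "FA_referral", "undefined_IBMFS", "not_eligible"
]


@dataclass(frozen=True)
class BeaconSet:
    consanguinity: bool = False
    endogamy: bool = False
    isonymy: bool = False
    family_hematologic: bool = False
    personal_early_malignancy: bool = False
    fgr_or_sga: bool = False
    physical_alterations: bool = False

    @property
    def any(self) -> bool:
        return any(getattr(self, f.name) for f in self.__dataclass_fields__.values())  # type: ignore[attr-defined]


@dataclass
class RuleFinding:
    syndrome: Syndrome
    fired: bool
    matched_criteria: list[tuple[str, str]] = field(default_factory=list)
    missing_criteria: list[str] = field(default_factory=list)
    score: int = 0
    pathway: Literal["hematologic+phenotype", "phenotype_only", "none"] = "none"
    actions: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


@dataclass
class SuspicionResult:
    patient_id: str
    eligible: bool
    eligibility_reasons: list[str]
    excluded_as: Literal["acquired", "FA_confirmed", "none"]
    exclusion_evidence: list[str]
    findings: list[RuleFinding]
    primary: Primary
    beacons: BeaconSet
    audit: list[str]

    def finding(self, syndrome: Syndrome) -> RuleFinding:
        return next(f for f in self.findings if f.syndrome == syndrome)


# -- beacon classes that make a feature a "physical alteration": short
# stature, visceral/skeletal malformation, dysmorphic features.
_PHYSICAL_SYSTEMS = frozenset({
    "growth", "skeletal", "craniofacial", "integument", "cardiac",
    "genitourinary", "gastrointestinal", "pancreatic", "ocular", "ear",
    "liver", "respiratory", "oral", "neck",
})


def detect_beacons(record: PatientRecord, catalog: FeatureCatalog,
                   config: RunConfig = RunConfig()) -> BeaconSet:
    fam = record.family
    pop = fam.settlement_population
    systems = catalog.organ_systems_hit(record.feature_ids)
    return BeaconSet(
        consanguinity=fam.consanguinity_degree is not None,
        endogamy=pop is not None and pop < config.thresholds.settlement_endogamy_max,
        isonymy=fam.shared_surname is True,
        family_hematologic=fam.hematological_disorder_in_family is True,
        personal_early_malignancy=bool(record.personal_malignancy),
        fgr_or_sga=record.prenatal.fgr is True or record.prenatal.sga is True,
        physical_alterations=bool(systems & _PHYSICAL_SYSTEMS),
    )


def check_eligibility(
    record: PatientRecord,
    profile: HematologyProfile,
    catalog: FeatureCatalog,
    config: RunConfig = RunConfig(),
) -> tuple[bool, list[str]]:
    reasons: list[str] = []
    systems = catalog.organ_systems_hit(record.feature_ids)
    non_heme = systems & (_PHYSICAL_SYSTEMS | {"neurological"})

    presentation = False
    if profile.any_cytopenia:
        presentation = True
        reasons.append(f"cytopenia ({profile.worst_class.value})")
    if any(catalog.matches(t, "HP:0001871") for t in record.feature_ids):
        presentation = True
        reasons.append("hematologic feature annotated")
    if len(non_heme) >= 2:
        presentation = True
        reasons.append(
            "≥2 non-hematological manifestations in distinct organ systems: "
            + ", ".join(sorted(non_heme))
        )

    beacons = detect_beacons(record, catalog, config)
    support = False
    if beacons.consanguinity or beacons.endogamy or beacons.family_hematologic:
        support = True
        reasons.append("positive family history")
    if beacons.physical_alterations:
        support = True
        reasons.append("physical abnormality")
    if (
        profile.onset_age_years is not None
        and profile.onset_age_years < config.thresholds.adult_onset_age
    ):
        support = True
        reasons.append(f"hematologic onset at {profile.onset_age_years:g} y (<18)")

    if not presentation:
        reasons.append("no qualifying hematologic or multi-system presentation")
    if not support:
        reasons.append("no family-history / physical-abnormality / pediatric-onset criterion")
    return presentation and support, reasons


def exclusion_gate(
    record: PatientRecord,
) -> tuple[Literal["acquired", "FA_confirmed", "none"], list[str]]:
    labs = record.labs
    if labs.deb_test == "positive":
        return "FA_confirmed", ["positive DEB chromosomal breakage test"]
    evidence = []
    for name in ("nutritional_deficiency", "viral_serology_positive",
                 "drug_radiation_exposure", "pnh_clone"):
        value = getattr(labs, name)
        if value is True:
            evidence.append(name)
    if evidence:
        return "acquired", evidence
    incomplete = [
        name for name in ("nutritional_deficiency", "viral_serology_positive",
                          "drug_radiation_exposure", "pnh_clone")
        if getattr(labs, name) is None
    ]
    if labs.deb_test == "not_done":
        incomplete.append("deb_test")
    return "none", [f"incomplete work-up: {n}" for n in incomplete]


def _hits(record: PatientRecord, catalog: FeatureCatalog, group: str) -> set[str]:
    return catalog.group_hits(record.feature_ids, group)


def _as_matched(catalog: FeatureCatalog, hits: set[str], tag: str) -> list[tuple[str, str]]:
    return [(tag, f"{t} ({catalog.label_of(t)})") for t in sorted(hits)]


def evaluate_dc(record: PatientRecord, profile: HematologyProfile,
                catalog: FeatureCatalog) -> RuleFinding:
    triad = _hits(record, catalog, "dc_triad")
    supportive = _hits(record, catalog, "dc_supportive")
    matched = _as_matched(catalog, triad, "triad") + _as_matched(catalog, supportive, "supportive")
    missing = [f"triad:{t}" for t in sorted(catalog.groups["dc_triad"] - triad)]
    f = RuleFinding("DC", fired=False, matched_criteria=matched,
                    missing_criteria=missing, score=len(triad) + len(supportive))
    if profile.any_cytopenia and triad:
        f.fired, f.pathway = True, "hematologic+phenotype"
    elif len(triad) == 3:
        f.fired, f.pathway = True, "phenotype_only"
    if f.fired:
        f.actions.append("order leukocyte telomere length test")
    return f


def evaluate_sds(record: PatientRecord, profile: HematologyProfile,
                 catalog: FeatureCatalog) -> RuleFinding:
    assoc = _hits(record, catalog, "sds_associated")
    ffqt_pos = record.labs.ffqt == "positive"
    if ffqt_pos:
        # a positive fecal-fat test asserts exocrine pancreatic
        # insufficiency even without the HPO annotation
        assoc = assoc | {"HP:0001738"}
    matched = _as_matched(catalog, assoc, "associated")
    if ffqt_pos:
        matched.append(("lab", "positive 72-h fecal fat qualitative test"))
    f = RuleFinding("SDS", fired=False, matched_criteria=matched,
                    missing_criteria=[], score=len(assoc))
    if profile.any_cytopenia and len(assoc) >= 3:
        f.fired, f.pathway = True, "hematologic+phenotype"
    elif ffqt_pos and profile.any_cytopenia:
        f.fired, f.pathway = True, "hematologic+phenotype"
    elif ffqt_pos:
        f.fired, f.pathway = True, "phenotype_only"
    else:
        need = max(0, 3 - len(assoc))
        f.missing_criteria = [f"{need} more associated feature(s) or positive FFQT"]
    if f.fired:
        f.actions.append("order serum trypsinogen / pancreatic isoamylase")
    return f


def evaluate_dba(record: PatientRecord, profile: HematologyProfile,
                 catalog: FeatureCatalog) -> RuleFinding:
    minor = _hits(record, catalog, "dba_minor")
    matched = _as_matched(catalog, minor, "minor")
    f = RuleFinding("DBA", fired=False, matched_criteria=matched,
                    missing_criteria=[], score=len(minor))
    if profile.macrocytic_anemia_with_reticulocytopenia is True:
        f.fired, f.pathway = True, "hematologic+phenotype"
        f.matched_criteria.insert(0, ("cbc", "macrocytic anemia with reticulocytopenia"))
        f.score += 1
        f.actions.append("order erythrocyte adenosine deaminase (eADA) screening")
        if (
            profile.onset_age_years is not None
            and profile.onset_age_years < 1.0
            and "erythroid_paucity" in record.labs.bm_biopsy
        ):
            f.flags.append("classic_dba")
    else:
        f.missing_criteria = ["macrocytic anemia with reticulocytopenia"]
    return f


def evaluate_tar(record: PatientRecord, profile: HematologyProfile,
                 catalog: FeatureCatalog) -> RuleFinding:
    radial = _hits(record, catalog, "tar_radial")
    thumbs_absent = bool(_hits(record, catalog, "thumb_absence"))
    supportive = _hits(record, catalog, "tar_supportive")
    thrombo = profile.ever_status.thrombocytopenia == "present"
    matched = _as_matched(catalog, radial, "radial_ray") + _as_matched(
        catalog, supportive, "supportive")
    f = RuleFinding("TAR", fired=False, matched_criteria=matched,
                    missing_criteria=[],
                    score=(1 if radial else 0) + len(supportive))
    if thrombo and radial and not thumbs_absent:
        f.fired, f.pathway = True, "hematologic+phenotype"
    else:
        if not thrombo:
            f.missing_criteria.append("thrombocytopenia")
        if not radial:
            f.missing_criteria.append("radial-ray alteration")
        if thumbs_absent:
            f.missing_criteria.append("thumbs preserved (absent thumb asserted)")
            f.flags.append("fa_cross_flag:absent_thumb_with_radial_ray")
    return f


def evaluate_scn(record: PatientRecord, profile: HematologyProfile,
                 catalog: FeatureCatalog) -> RuleFinding:
    assoc = _hits(record, catalog, "scn_associated")
    lifelong = profile.persistent_neutropenia or profile.cyclic_neutropenia
    matched = _as_matched(catalog, assoc, "associated")
    if profile.persistent_neutropenia:
        matched.insert(0, ("cbc", "persistent neutropenia"))
    if profile.cyclic_neutropenia:
        matched.insert(0, ("cbc", "cyclic neutropenia"))
    f = RuleFinding("SCN", fired=False, matched_criteria=matched,
                    missing_criteria=[], score=len(assoc))
    if lifelong and len(assoc) >= 2:
        f.fired, f.pathway = True, "hematologic+phenotype"
    else:
        if not lifelong:
            f.missing_criteria.append("persistent or cyclic neutropenia")
        if len(assoc) < 2:
            f.missing_criteria.append(f"{2 - len(assoc)} more associated feature(s)")
    return f


def evaluate_fa(record: PatientRecord, profile: HematologyProfile,
                catalog: FeatureCatalog) -> RuleFinding:
    vacterl = _hits(record, catalog, "vacterl_h")
    phenos = _hits(record, catalog, "phenos")
    hits = vacterl | phenos
    matched = _as_matched(catalog, vacterl, "vacterl_h") + _as_matched(
        catalog, phenos, "phenos")
    f = RuleFinding("FA", fired=False, matched_criteria=matched,
                    missing_criteria=[], score=len(hits))
    if profile.any_cytopenia and hits:
        f.fired, f.pathway = True, "hematologic+phenotype"
    elif len(hits) >= 3:
        f.fired, f.pathway = True, "phenotype_only"
    if f.fired and record.labs.deb_test == "not_done":
        f.actions.append("order DEB chromosomal breakage test")
    return f


def classify(
    record: PatientRecord,
    catalog: FeatureCatalog | None = None,
    config: RunConfig = RunConfig(),
) -> SuspicionResult:
    """Run the full decision algorithm on one record."""
    cat = catalog if catalog is not None else load_catalog()
    audit: list[str] = []
    profile = hematology_profile(record, cat, config.thresholds)
    audit.append(
        f"profile: class={profile.worst_class.value} onset={profile.onset_age_years} "
        f"({profile.onset_category}) td={profile.transfusion_dependent} "
        f"persistent_n={profile.persistent_neutropenia} cyclic_n={profile.cyclic_neutropenia} "
        f"macro+retic={profile.macrocytic_anemia_with_reticulocytopenia}"
    )
    beacons = detect_beacons(record, cat, config)
    audit.append(f"beacons: {beacons}")

    eligible, reasons = check_eligibility(record, profile, cat, config)
    audit.append(f"eligibility: {eligible} ({'; '.join(reasons)})")
    if not eligible:
        return SuspicionResult(record.patient_id, False, reasons, "none", [],
                               [], "not_eligible", beacons, audit)

    excluded_as, evidence = exclusion_gate(record)
    audit.append(f"exclusion gate: {excluded_as} ({'; '.join(evidence) or 'clean'})")
    if excluded_as != "none":
        # terminal: acquired cause or confirmed FA; no rules evaluated
        return SuspicionResult(record.patient_id, True, reasons, excluded_as,
                               evidence, [], "not_eligible", beacons, audit)

    findings = [
        evaluate_tar(record, profile, cat),
        evaluate_scn(record, profile, cat),
        evaluate_dc(record, profile, cat),
        evaluate_sds(record, profile, cat),
        evaluate_dba(record, profile, cat),
        evaluate_fa(record, profile, cat),
    ]
    for f in findings:
        audit.append(
            f"rule {f.syndrome}: fired={f.fired} pathway={f.pathway} score={f.score}"
        )

    by_syndrome = {f.syndrome: f for f in findings}
    fired_specific = [s for s in config.precedence if by_syndrome[s].fired]
    fa = by_syndrome["FA"]

    primary: Primary
    if fired_specific:
        primary = fired_specific[0]  # type: ignore[assignment]
        if len(fired_specific) > 1:
            others = ", ".join(
                f"{s} (score {by_syndrome[s].score})" for s in fired_specific[1:]
            )
            audit.append(f"precedence: {primary} over {others}")
    elif fa.fired and record.labs.deb_test == "not_done":
        primary = "FA_referral"
        audit.append("FA pattern fired exclusively with DEB not done -> referral")
    elif fa.fired:
        primary = "undefined_IBMFS"
        audit.append("FA pattern fired but DEB test negative -> undefined IBMFS")
    else:
        primary = "undefined_IBMFS"
        audit.append("no rule fired -> undefined IBMFS")
    return SuspicionResult(record.patient_id, True, reasons, "none", evidence,
                           findings, primary, beacons, audit)
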