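"""Decision algorithm: gates, beacons, per-syndrome rules, precedence."""

import dataclasses

import pytest

from ibmfs.config import RunConfig
from ibmfs.hematology import hematology_profile
from ibmfs.records import CBCMeasurement, FamilyHistory, LabPanel, PatientRecord
from ibmfs.triage import (
    check_eligibility,
    classify,
    detect_beacons,
    evaluate_dba,
    evaluate_dc,
    evaluate_fa,
    evaluate_scn,
    evaluate_sds,
    evaluate_tar,
    exclusion_gate,
)

CFG = RunConfig()


def cbc(age=2.0, hb=13.0, mcv=85.0, anc=3000.0, plt=250_000.0, retic=50.0):
    return CBCMeasurement(age_years=age, hb=hb, mcv=mcv, anc=anc,
                          platelets=plt, reticulocytes=retic)


def make(features=(), series=(), **over):
    base = dict(
        patient_id="T", age_years=8.0,
        features=[{"term_id": t} for t in features],
        cbc_series=list(series),
    )
    base.update(over)
    return PatientRecord(**base)


def prof(record, catalog):
    return hematology_profile(record, catalog, CFG.thresholds)


ANEMIC_THROMBO = [cbc(hb=9.0, plt=90_000)]
THROMBO = [cbc(plt=80_000)]
DBA_SERIES = [cbc(hb=7.5, mcv=108, retic=8)]
CYCLIC = [cbc(age=a, anc=v) for a, v in
          [(1, 1800), (2, 300), (3, 1700), (4, 250), (5, 1600)]]


class TestEligibility:
    def test_bicytopenia_with_pediatric_onset(self, catalog):
        r = make(series=ANEMIC_THROMBO)
        ok, reasons = check_eligibility(r, prof(r, catalog), catalog)
        assert ok
        assert any("onset" in s for s in reasons)

    def test_nothing_at_all(self, catalog):
        r = make()
        ok, _ = check_eligibility(r, prof(r, catalog), catalog)
        assert not ok

    def test_two_organ_systems_plus_consanguinity_without_cytopenia(self, catalog):
        r = make(features=["HP:0001738", "HP:0004322"],
                 family=FamilyHistory(consanguinity_degree=2))
        ok, reasons = check_eligibility(r, prof(r, catalog), catalog)
        assert ok
        assert any("family history" in s for s in reasons)

    def test_two_terms_in_one_system_do_not_count_twice(self, catalog):
        # two craniofacial terms = one organ system; no cytopenia
        r = make(features=["HP:0000414", "HP:0000276"])
        ok, _ = check_eligibility(r, prof(r, catalog), catalog)
        assert not ok


class TestExclusionGate:
    def test_deb_positive_is_confirmed_fa(self, catalog):
        r = make(labs=LabPanel(deb_test="positive"))
        assert exclusion_gate(r)[0] == "FA_confirmed"

    def test_all_negative(self):
        labs = LabPanel(deb_test="negative", viral_serology_positive=False,
                        nutritional_deficiency=False, drug_radiation_exposure=False,
                        pnh_clone=False)
        verdict, evidence = exclusion_gate(make(labs=labs))
        assert verdict == "none"
        assert evidence == []

    def test_nutritional_deficiency_is_acquired(self):
        verdict, evidence = exclusion_gate(
            make(labs=LabPanel(nutritional_deficiency=True)))
        assert verdict == "acquired"
        assert "nutritional_deficiency" in evidence

    def test_unknown_never_excludes_but_is_flagged(self):
        verdict, evidence = exclusion_gate(make())
        assert verdict == "none"
        assert any("incomplete" in e for e in evidence)


class TestBeacons:
    def test_small_settlement_is_endogamy(self, catalog):
        r = make(family=FamilyHistory(settlement_population=3000))
        assert detect_beacons(r, catalog).endogamy is True

    def test_large_settlement_is_not(self, catalog):
        r = make(family=FamilyHistory(settlement_population=50_000))
        assert detect_beacons(r, catalog).endogamy is False

    def test_all_unknown_all_false(self, catalog):
        b = detect_beacons(make(), catalog)
        assert not b.any

    def test_third_degree_consanguinity(self, catalog):
        r = make(family=FamilyHistory(consanguinity_degree=3))
        assert detect_beacons(r, catalog).consanguinity is True

    def test_short_stature_is_physical_alteration(self, catalog):
        assert detect_beacons(make(features=["HP:0004322"]), catalog).physical_alterations


class TestDCRule:
    def test_cytopenia_plus_one_triad_element(self, catalog):
        r = make(features=["HP:0002164"], series=THROMBO)
        f = evaluate_dc(r, prof(r, catalog), catalog)
        assert f.fired and f.pathway == "hematologic+phenotype"

    def test_pancytopenia_without_triad_does_not_fire(self, catalog):
        r = make(series=[cbc(hb=8, anc=300, plt=40_000)])
        assert not evaluate_dc(r, prof(r, catalog), catalog).fired

    def test_complete_triad_with_normal_cbc_fires_phenotype_only(self, catalog):
        r = make(features=["HP:0002745", "HP:0002164", "HP:0007427"], series=[cbc()])
        f = evaluate_dc(r, prof(r, catalog), catalog)
        assert f.fired and f.pathway == "phenotype_only"


class TestSDSRule:
    def test_neutropenia_plus_three_features(self, catalog):
        r = make(features=["HP:0001738", "HP:0004322", "HP:0002024"],
                 series=[cbc(anc=800)])
        assert evaluate_sds(r, prof(r, catalog), catalog).fired

    def test_two_features_below_cutoff(self, catalog):
        r = make(features=["HP:0004322", "HP:0002024"], series=[cbc(anc=800)])
        assert not evaluate_sds(r, prof(r, catalog), catalog).fired

    def test_positive_ffqt_without_cytopenia_phenotype_only(self, catalog):
        r = make(series=[cbc()], labs=LabPanel(ffqt="positive"))
        f = evaluate_sds(r, prof(r, catalog), catalog)
        assert f.fired and f.pathway == "phenotype_only"


class TestDBARule:
    def test_macrocytic_anemia_with_reticulocytopenia_fires(self, catalog):
        r = make(features=["HP:0000414"], series=DBA_SERIES)
        f = evaluate_dba(r, prof(r, catalog), catalog)
        assert f.fired
        # one minor feature matched (bulbous nasal tip -> craniofacial)
        assert any("HP:0001999" in ev for _, ev in f.matched_criteria)

    def test_normocytic_anemia_does_not_fire(self, catalog):
        r = make(series=[cbc(hb=9.0, mcv=85)])
        assert not evaluate_dba(r, prof(r, catalog), catalog).fired

    def test_classic_dba_flag(self, catalog):
        r = make(series=[cbc(age=0.7, hb=7.0, mcv=108, retic=6)],
                 labs=LabPanel(bm_biopsy=["erythroid_paucity"]))
        f = evaluate_dba(r, prof(r, catalog), catalog)
        assert "classic_dba" in f.flags


class TestTARRule:
    def test_thrombocytopenia_with_radial_agenesis_and_thumbs(self, catalog):
        r = make(features=["HP:0003974"], series=THROMBO)
        assert evaluate_tar(r, prof(r, catalog), catalog).fired

    def test_thrombocytopenia_with_normal_limbs(self, catalog):
        r = make(series=THROMBO)
        assert not evaluate_tar(r, prof(r, catalog), catalog).fired

    def test_absent_thumb_vetoes_and_raises_fa_cross_flag(self, catalog):
        r = make(features=["HP:0003974", "HP:0009777"], series=THROMBO)
        f = evaluate_tar(r, prof(r, catalog), catalog)
        assert not f.fired
        assert any("fa_cross_flag" in fl for fl in f.flags)

    def test_hypoplastic_thumb_does_not_veto(self, catalog):
        r = make(features=["HP:0003974", "HP:0009601"], series=THROMBO)
        assert evaluate_tar(r, prof(r, catalog), catalog).fired


class TestSCNRule:
    def test_persistent_neutropenia_with_two_features(self, catalog):
        r = make(features=["HP:0004322", "HP:0001627"],
                 series=[cbc(age=a, anc=300) for a in (1, 2, 3)])
        assert evaluate_scn(r, prof(r, catalog), catalog).fired

    def test_isolated_neutropenic_cbc_is_not_persistent(self, catalog):
        series = [cbc(age=1, anc=400)] + [cbc(age=a, anc=3000) for a in (2, 3)]
        r = make(features=["HP:0004322", "HP:0001627"], series=series)
        assert not evaluate_scn(r, prof(r, catalog), catalog).fired

    def test_one_associated_feature_insufficient(self, catalog):
        r = make(features=["HP:0004322"],
                 series=[cbc(age=a, anc=300) for a in (1, 2, 3)])
        assert not evaluate_scn(r, prof(r, catalog), catalog).fired

    def test_cyclic_pattern_counts_as_lifelong(self, catalog):
        r = make(features=["HP:0004322", "HP:0000119"], series=CYCLIC)
        assert evaluate_scn(r, prof(r, catalog), catalog).fired


class TestFARule:
    def test_cytopenia_plus_phenos_feature(self, catalog):
        r = make(features=["HP:0000957", "HP:0000252"], series=DBA_SERIES)
        f = evaluate_fa(r, prof(r, catalog), catalog)
        assert f.fired
        assert any("DEB" in a for a in f.actions)

    def test_three_terms_without_cytopenia(self, catalog):
        r = make(features=["HP:0009777", "HP:0000077", "HP:0004322"], series=[cbc()])
        f = evaluate_fa(r, prof(r, catalog), catalog)
        assert f.fired and f.pathway == "phenotype_only"

    def test_nothing_does_not_fire(self, catalog):
        r = make(series=[cbc()])
        assert not evaluate_fa(r, prof(r, catalog), catalog).fired


class TestClassify:
    def test_dc_archetype(self, catalog):
        r = make(features=["HP:0002745", "HP:0002164", "HP:0007427"],
                 series=[cbc(plt=60_000)], labs=LabPanel(deb_test="negative"))
        assert classify(r, catalog).primary == "DC"

    def test_eligible_firing_nothing_is_undefined(self, catalog):
        r = make(features=["HP:0000414"], series=ANEMIC_THROMBO,
                 labs=LabPanel(deb_test="negative"))
        res = classify(r, catalog)
        assert res.primary == "undefined_IBMFS"
        assert res.eligible

    def test_tar_beats_dba_with_audit(self, catalog):
        series = [cbc(hb=7.5, mcv=108, plt=60_000, retic=8)]
        r = make(features=["HP:0003974"], series=series,
                 labs=LabPanel(deb_test="negative"))
        res = classify(r, catalog)
        assert res.primary == "TAR"
        assert res.finding("DBA").fired
        assert any("precedence" in line for line in res.audit)

    def test_fa_pattern_with_deb_not_done_is_referral(self, catalog):
        r = make(features=["HP:0000957"], series=ANEMIC_THROMBO)
        res = classify(r, catalog)
        assert res.primary == "FA_referral"

    def test_fa_pattern_with_deb_negative_is_undefined(self, catalog):
        r = make(features=["HP:0000957"], series=ANEMIC_THROMBO,
                 labs=LabPanel(deb_test="negative"))
        assert classify(r, catalog).primary == "undefined_IBMFS"

    def test_excluded_record_gets_no_findings(self, catalog):
        r = make(series=ANEMIC_THROMBO, labs=LabPanel(viral_serology_positive=True))
        res = classify(r, catalog)
        assert res.excluded_as == "acquired"
        assert res.findings == []

    def test_not_eligible_record(self, catalog):
        res = classify(make(), catalog)
        assert res.primary == "not_eligible"

    def test_deterministic_including_audit(self, catalog):
        r = make(features=["HP:0002164"], series=THROMBO,
                 labs=LabPanel(deb_test="negative"))
        assert classify(r, catalog) == classify(r, catalog)

    def test_unknowns_never_flip_exclusion(self, catalog):
        labs = LabPanel(deb_test="negative", viral_serology_positive=False,
                        nutritional_deficiency=False, drug_radiation_exposure=False,
                        pnh_clone=False)
        r = make(features=["HP:0002164"], series=THROMBO, labs=labs)
        baseline = classify(r, catalog)
        assert baseline.excluded_as == "none"
        for field in ("viral_serology_positive", "nutritional_deficiency",
                      "drug_radiation_exposure", "pnh_clone"):
            weakened = r.model_copy(deep=True)
            setattr(weakened.labs, field, None)
            assert classify(weakened, catalog).excluded_as == "none"

    def test_precedence_override_via_config(self, catalog):
        series = [cbc(hb=7.5, mcv=108, plt=60_000, retic=8)]
        r = make(features=["HP:0003974"], series=series,
                 labs=LabPanel(deb_test="negative"))
        cfg = dataclasses.replace(CFG, precedence=("DBA", "TAR", "SCN", "DC", "SDS"))
        assert classify(r, catalog, cfg).primary == "DBA"
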