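"""CBC interpretation: grading partitions, windows, onset, aggregation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibmfs.config import Thresholds
from ibmfs.hematology import (
    classify_anemia,
    cyclic_pattern,
    cytopenia_class,
    grade_neutropenia,
    hematology_profile,
    lineage_status,
    onset,
    onset_category,
    persistent_neutropenia,
    transfusion_dependent,
)
from ibmfs.records import CBCMeasurement, PatientRecord, TransfusionEvent

REF = Thresholds()


def cbc(age=5.0, hb=13.0, mcv=85.0, anc=3000.0, plt=250_000.0, retic=50.0):
    return CBCMeasurement(age_years=age, hb=hb, mcv=mcv, anc=anc,
                          platelets=plt, reticulocytes=retic)


class TestNeutropeniaGrading:
    @pytest.mark.parametrize(
        "anc, grade",
        [
            (400, "severe"), (499, "severe"), (500, "moderate"), (999, "moderate"),
            (1000, "mild"), (1499, "mild"), (1500, "none"), (3000, "none"), (0, "severe"),
        ],
    )
    def test_half_open_bands(self, anc, grade):
        assert grade_neutropenia(anc) == grade

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            grade_neutropenia(-1)

    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
    @settings(derandomize=True)
    def test_partition_exhaustive_and_exclusive(self, anc):
        grade = grade_neutropenia(anc)
        expected = ("severe" if anc < 500 else "moderate" if anc < 1000
                    else "mild" if anc < 1500 else "none")
        assert grade == expected


class TestAnemia:
    def test_macrocytic(self):
        assert classify_anemia(9.0, 102, 4.0)[0] == "macrocytic"

    def test_not_anemic(self):
        assert classify_anemia(12.0, 85, 4.0)[0] == "none"

    def test_normocytic_at_default_thresholds(self):
        assert classify_anemia(10.4, 80, 4.0)[0] == "normocytic"

    def test_unknown_mcv_defaults_normocytic_with_flag(self):
        status, flags = classify_anemia(9.0, None, 4.0)
        assert status == "normocytic"
        assert flags == ["mcv_unknown_default_normocytic"]

    def test_threshold_boundary_not_anemic(self):
        assert classify_anemia(10.5, 85, 4.0)[0] == "none"


class TestCytopeniaClass:
    @pytest.mark.parametrize(
        "kwargs, value, lineages",
        [
            (dict(hb=8, anc=300, plt=40_000), "pancytopenia",
             {"erythroid", "myeloid", "megakaryocytic"}),
            (dict(hb=14, anc=3000, plt=250_000), "none", set()),
            (dict(hb=9, anc=2000, plt=100_000), "bilineage",
             {"erythroid", "megakaryocytic"}),
            (dict(hb=13, anc=3000, plt=140_000), "unilineage", {"megakaryocytic"}),
        ],
    )
    def test_class_from_lineage_count(self, kwargs, value, lineages):
        cls = cytopenia_class(lineage_status(cbc(**kwargs)))
        assert cls.value == value
        assert cls.affected_lineages == frozenset(lineages)


def rbc(day):
    return TransfusionEvent(age_days=day, product="RBC", units=1)


class TestTransfusionDependency:
    @pytest.mark.parametrize(
        "days, expected",
        [
            ([0, 20], True),
            ([0], False),
            ([0, 29, 58], False),   # 29-day gaps never fit one window
            ([0, 28, 58], True),    # inclusive 28-day span counts
            ([], False),
        ],
    )
    def test_window_rule(self, days, expected):
        assert transfusion_dependent([rbc(d) for d in days]) is expected

    def test_non_rbc_products_ignored(self):
        events = [TransfusionEvent(age_days=d, product="platelet", units=2) for d in (0, 5)]
        assert transfusion_dependent(events) is False

    def test_multi_unit_single_event_counts(self):
        assert transfusion_dependent([TransfusionEvent(age_days=3, product="RBC", units=2)])

    def test_unsorted_input_sorted_internally(self):
        assert transfusion_dependent([rbc(20), rbc(0)]) is True


class TestOnset:
    @pytest.mark.parametrize(
        "age, cat",
        [(0.7, "le2"), (2.0, "le2"), (2.01, "gt2_le5"), (5.0, "gt2_le5"),
         (5.01, "gt5_lt18"), (17.99, "gt5_lt18"), (18.0, "adult"), (None, "none")],
    )
    def test_category_boundaries(self, age, cat):
        assert onset_category(age) == cat

    def test_first_abnormal_cbc(self):
        series = [cbc(age=0.5), cbc(age=0.7, plt=90_000), cbc(age=1.0, plt=80_000)]
        assert onset(series) == (0.7, "le2")

    def test_never_abnormal(self):
        assert onset([cbc(age=1.0), cbc(age=2.0)]) == (None, "none")

    def test_feature_fallback_when_no_series(self, catalog):
        got = onset([], [("HP:0001915", 7.0), ("HP:0004322", 1.0)], catalog)
        assert got == (7.0, "gt5_lt18")  # short stature is not hematologic


class TestNeutropeniaPatterns:
    def test_all_severe_is_persistent(self):
        series = [cbc(age=a, anc=300) for a in (1, 2, 3)]
        assert persistent_neutropenia(series) is True

    def test_single_normal_series(self):
        assert persistent_neutropenia([cbc()]) is False
        assert cyclic_pattern([cbc()]) is False

    def test_recovery_above_ceiling_breaks_persistence(self):
        series = [cbc(age=a, anc=v) for a, v in [(1, 300), (2, 400), (3, 2600)]]
        assert persistent_neutropenia(series) is False

    def test_cyclic_crossings(self):
        ancs = [1800, 300, 1700, 250, 1600]
        series = [cbc(age=i + 1, anc=v) for i, v in enumerate(ancs)]
        assert cyclic_pattern(series) is True

    def test_cyclic_needs_nadir_below_500(self):
        ancs = [1800, 900, 1700, 800, 1600]
        series = [cbc(age=i + 1, anc=v) for i, v in enumerate(ancs)]
        assert cyclic_pattern(series) is False

    def test_cyclic_needs_four_measurements(self):
        series = [cbc(age=i + 1, anc=v) for i, v in enumerate([1800, 300, 1700])]
        assert cyclic_pattern(series) is False


def record(series, **over):
    base = dict(patient_id="T", age_years=10.0, cbc_series=series)
    base.update(over)
    return PatientRecord(**base)


class TestProfile:
    def test_macrocytic_with_reticulocytopenia_flag(self, catalog):
        prof = hematology_profile(record([cbc(hb=8, mcv=108, retic=10)]), catalog)
        assert prof.macrocytic_anemia_with_reticulocytopenia is True

    def test_flag_unknown_when_retics_missing(self, catalog):
        m = CBCMeasurement(age_years=1, hb=8, mcv=108, anc=3000, platelets=250_000)
        prof = hematology_profile(record([m]), catalog)
        assert prof.macrocytic_anemia_with_reticulocytopenia is None

    def test_empty_series_all_none(self, catalog):
        prof = hematology_profile(record([]), catalog)
        assert prof.worst_class.value == "none"
        assert prof.onset_category == "none"
        assert not prof.transfusion_dependent

    def test_single_platelet_dip_recorded_in_ever_status(self, catalog):
        series = [cbc(age=1), cbc(age=2, plt=140_000), cbc(age=3)]
        prof = hematology_profile(record(series), catalog)
        assert prof.ever_status.thrombocytopenia == "present"
        assert prof.worst_class.value == "unilineage"

    @given(
        hb=st.floats(5, 16), anc=st.floats(0, 4000), plt=st.floats(1e4, 4e5),
        d_hb=st.floats(0, 3), d_anc=st.floats(0, 1500), d_plt=st.floats(0, 1e5),
    )
    @settings(derandomize=True, max_examples=60)
    def test_worsening_any_value_never_improves_profile(
        self, catalog, hb, anc, plt, d_hb, d_anc, d_plt
    ):
        rank = {"none": 0, "unilineage": 1, "bilineage": 2, "pancytopenia": 3}
        base = hematology_profile(record([cbc(hb=hb, anc=anc, plt=plt)]), catalog)
        worse = hematology_profile(
            record([cbc(hb=hb - d_hb, anc=max(0, anc - d_anc), plt=max(0, plt - d_plt))]),
            catalog,
        )
        assert rank[worse.worst_class.value] >= rank[base.worst_class.value]
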