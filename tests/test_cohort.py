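"""Covariate-derivation rules: boundary behaviour and partition properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esrref import (
    InvalidInputError,
    MissingDataError,
    ParticipantRecord,
    alcohol_category,
    alcohol_grams_per_week,
    bmi_and_class,
    derive_table,
    ipaq_classify,
    metabolic_syndrome,
    read_cohort_csv,
    smoking_category,
    write_derived_csv,
)
from esrref.cohort import ActivityCategory, AlcoholCategory, BMIClass, SmokingCategory


def make_record(**overrides) -> ParticipantRecord:
    base = dict(
        id="x", age=40.0, sex="female",
        wine_glasses_per_week=0.0, beers_per_week=0.0, spirits_per_week=0.0,
        cigarettes_per_day=0.0, years_since_quit=None, ever_smoked=False,
        vigorous_days=0, moderate_days=0, walking_days=0,
        vigorous_min_per_day=0.0, moderate_min_per_day=0.0, walking_min_per_day=0.0,
        weight=65.0, height=1.65, waist=80.0, triglycerides=100.0, hdl=60.0,
        systolic_bp=110.0, diastolic_bp=70.0,
        on_antihypertensives=False, on_antidiabetics=False,
        glucose=90.0, hemoglobin=13.5, mcv=90.0, esr=10.0,
    )
    base.update(overrides)
    return ParticipantRecord(**base)


class TestAlcohol:
    @pytest.mark.parametrize("wine,beer,spirits,grams", [
        (7, 0, 0, 70.0),
        (0, 0, 0, 0.0),
        (0, 0, 14, 280.0),
        (2, 3, 1, 70.0),
    ])
    def test_unit_masses(self, wine, beer, spirits, grams):
        assert alcohol_grams_per_week(wine, beer, spirits) == grams

    def test_negative_count_rejected(self):
        with pytest.raises(InvalidInputError):
            alcohol_grams_per_week(-1, 0, 0)

    @pytest.mark.parametrize("grams,cat", [
        (0, AlcoholCategory.abstainer_occasional),
        (1, AlcoholCategory.light),
        (140, AlcoholCategory.light),
        (141, AlcoholCategory.moderate),
        (279, AlcoholCategory.moderate),
        (280, AlcoholCategory.heavy),
        (350, AlcoholCategory.heavy),
    ])
    def test_category_boundaries(self, grams, cat):
        assert alcohol_category(grams) == cat

    def test_negative_grams_rejected(self):
        with pytest.raises(InvalidInputError):
            alcohol_category(-5)

    @given(st.floats(min_value=0, max_value=2000), st.floats(min_value=0, max_value=2000))
    @settings(deadline=None)
    def test_category_monotone_in_grams(self, a, b):
        order = [
            AlcoholCategory.abstainer_occasional, AlcoholCategory.light,
            AlcoholCategory.moderate, AlcoholCategory.heavy,
        ]
        lo, hi = sorted([a, b])
        assert order.index(alcohol_category(lo)) <= order.index(alcohol_category(hi))


class TestSmoking:
    @pytest.mark.parametrize("cig,quit,ever,cat", [
        (1, None, True, SmokingCategory.smoker),
        (0, 0.5, True, SmokingCategory.smoker),
        (0, 1.0, True, SmokingCategory.smoker),   # quit exactly a year ago
        (0, 2, True, SmokingCategory.ex_smoker),
        (0, None, False, SmokingCategory.never),
    ])
    def test_classification(self, cig, quit, ever, cat):
        assert smoking_category(cig, quit, ever) == cat

    def test_contradictory_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            smoking_category(5, None, False)
        with pytest.raises(InvalidInputError):
            smoking_category(0, 2.0, False)

    @given(
        st.floats(min_value=0, max_value=60),
        st.one_of(st.none(), st.floats(min_value=0, max_value=60)),
    )
    @settings(deadline=None)
    def test_partition_exhaustive_and_exclusive(self, cig, quit):
        """Every consistent input maps onto exactly one of the three levels."""
        ever = cig >= 1 or quit is not None
        cat = smoking_category(cig, quit, ever)
        assert cat in set(SmokingCategory)


class TestBMI:
    def test_hand_computed_value(self):
        bmi, cls = bmi_and_class(80.0, 1.79)
        assert bmi == pytest.approx(24.97, abs=0.005)
        assert cls == BMIClass.normal

    @pytest.mark.parametrize("bmi,cls", [
        (24.99, BMIClass.normal),
        (25.0, BMIClass.overweight),
        (30.0, BMIClass.overweight),
        (30.5, BMIClass.obese),
    ])
    def test_class_boundaries(self, bmi, cls):
        height = 2.0  # weight = 4*bmi is exact in floating point
        assert bmi_and_class(bmi * height**2, height)[1] == cls

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            bmi_and_class(70.0, 0.0)
        with pytest.raises(InvalidInputError):
            bmi_and_class(-1.0, 1.7)


def independent_metsyn(rec: ParticipantRecord) -> int:
    """Re-statement of the five ATP-III comparisons, written separately
    from the implementation, for the brute-force cross-check."""
    male = rec.sex == "male"
    crits = [
        rec.waist > 102 if male else rec.waist > 88,
        rec.triglycerides >= 150,
        rec.hdl < 40 if male else rec.hdl < 50,
        rec.systolic_bp >= 130 or rec.diastolic_bp >= 85 or rec.on_antihypertensives,
        rec.glucose >= 110 or rec.on_antidiabetics,
    ]
    return sum(bool(c) for c in crits)


class TestMetabolicSyndrome:
    def test_three_criteria_at_boundaries(self):
        rec = make_record(sex="male", waist=103, triglycerides=150, hdl=39,
                          systolic_bp=120, diastolic_bp=80, glucose=100)
        assert metabolic_syndrome(rec) == (3, True)

    def test_all_below_thresholds_including_waist_88(self):
        rec = make_record(sex="female", waist=88, triglycerides=100, hdl=60,
                          systolic_bp=110, diastolic_bp=70, glucose=90)
        assert metabolic_syndrome(rec) == (0, False)

    def test_maximal_case(self):
        rec = make_record(sex="male", waist=110, triglycerides=200, hdl=30,
                          systolic_bp=150, diastolic_bp=95, glucose=130)
        assert metabolic_syndrome(rec) == (5, True)

    def test_missing_component_named(self):
        rec = make_record(waist=float("nan"))
        with pytest.raises(MissingDataError, match="waist"):
            metabolic_syndrome(rec)

    @given(
        sex=st.sampled_from(["male", "female"]),
        waist=st.floats(min_value=60, max_value=130),
        tg=st.floats(min_value=40, max_value=400),
        hdl=st.floats(min_value=20, max_value=90),
        sbp=st.floats(min_value=90, max_value=190),
        dbp=st.floats(min_value=50, max_value=115),
        glu=st.floats(min_value=60, max_value=250),
        aht=st.booleans(),
        adm=st.booleans(),
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_independent_reimplementation(
        self, sex, waist, tg, hdl, sbp, dbp, glu, aht, adm
    ):
        rec = make_record(sex=sex, waist=waist, triglycerides=tg, hdl=hdl,
                          systolic_bp=sbp, diastolic_bp=dbp, glucose=glu,
                          on_antihypertensives=aht, on_antidiabetics=adm)
        count, flag = metabolic_syndrome(rec)
        assert count == independent_metsyn(rec)
        assert flag == (count >= 3)


class TestIPAQ:
    def test_vigorous_three_days_twenty_minutes_is_moderate(self):
        met, cat = ipaq_classify(3, 20, 0, 0, 0, 0)
        assert cat == ActivityCategory.moderate

    def test_vigorous_met_over_1500_is_high(self):
        met, cat = ipaq_classify(3, 80, 0, 0, 0, 0)
        assert met == pytest.approx(3 * 80 * 8.0)
        assert cat == ActivityCategory.high

    def test_all_zero_is_low(self):
        assert ipaq_classify(0, 0, 0, 0, 0, 0) == (0.0, ActivityCategory.low)

    def test_seven_day_combination_3000_met_is_high(self):
        # 4 walking + 3 moderate days, high volume
        met, cat = ipaq_classify(0, 0, 3, 120, 4, 120)
        assert met >= 3000
        assert cat == ActivityCategory.high

    def test_thirty_minute_days_rule(self):
        met, cat = ipaq_classify(0, 0, 2, 35, 3, 40)
        assert cat == ActivityCategory.moderate

    def test_days_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            ipaq_classify(8, 20, 0, 0, 0, 0)

    @given(
        vd=st.integers(0, 7), vm=st.floats(0, 240),
        md=st.integers(0, 7), mm=st.floats(0, 240),
        wd=st.integers(0, 7), wm=st.floats(0, 240),
    )
    @settings(deadline=None, max_examples=200)
    def test_precedence_total_and_600_rule_never_low(self, vd, vm, md, mm, wd, wm):
        met, cat = ipaq_classify(vd, vm, md, mm, wd, wm)
        assert cat in set(ActivityCategory)
        # the >=5-days/600-MET moderate criterion can never leave "low"
        if vd + md + wd >= 5 and met >= 600:
            assert cat != ActivityCategory.low
        if cat == ActivityCategory.high:
            assert (vd >= 3 and met >= 1500) or (vd + md + wd >= 7 and met >= 3000)


class TestTableInterface:
    def test_csv_roundtrip_and_derivation(self, small_cohort, tmp_path):
        p = tmp_path / "cohort.csv"
        df = small_cohort.copy()
        for c in ("ever_smoked", "on_antihypertensives", "on_antidiabetics"):
            df[c] = df[c].astype(int)
        df.to_csv(p, index=False)
        back = read_cohort_csv(p)
        derived = derive_table(back)
        assert len(derived) == len(small_cohort)
        assert derived.attrs["n_excluded"] == 0
        out = tmp_path / "derived.csv"
        write_derived_csv(derived, out)
        again = pd.read_csv(out)
        assert list(again.columns) == list(derived.columns)

    def test_complete_case_exclusion_counted(self, small_cohort):
        df = small_cohort.copy()
        df.loc[df.index[:3], "glucose"] = np.nan
        derived = derive_table(df)
        assert derived.attrs["n_excluded"] == 3
        assert len(derived) == len(df) - 3

    def test_missing_column_reported(self, small_cohort):
        with pytest.raises(MissingDataError, match="esr"):
            derive_table(small_cohort.drop(columns=["esr"]))
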