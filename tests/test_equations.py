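"""Unit and property tests for the prediction equations and conversions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from iodine_status.equations import (
    ImplausibleInputError,
    InputError,
    Participant,
    PredictedCreatinine,
    Equation,
    Sex,
    SpotSample,
    Urine24h,
    creatinine_mg_to_mmol,
    creatinine_mmol_to_mg,
    intake_from_excretion,
    iom_intake,
    is_complete_collection,
    kawasaki_creatinine,
    mage_creatinine,
    measured_uie,
    predict_creatinine_kawasaki,
    predict_creatinine_mage,
    predict_creatinine_tanaka,
    predict_uie,
    predicted_uie,
    tanaka_creatinine,
)

from oracles import (
    iom_intake_oracle,
    kawasaki_female_oracle,
    kawasaki_male_oracle,
    mage_oracle,
    pruie_oracle,
    tanaka_oracle,
)


def participant(sex="female", age=50.0, weight=70.0, height=165.0, **kw):
    return Participant(id="p", sex=sex, age=age, weight=weight, height=height, **kw)


# plausible adult ranges used throughout
ages = st.floats(18, 90)
weights = st.floats(40, 150)
heights = st.floats(140, 200)


class TestTanaka:
    def test_longhand_examples(self):
        assert predict_creatinine_tanaka(participant(age=50, weight=70, height=165)
                                         ).prcr_mg_day == pytest.approx(1358.95)
        assert predict_creatinine_tanaka(participant(age=20, weight=80, height=180)
                                         ).prcr_mg_day == pytest.approx(1811.15)

    def test_linear_in_age(self):
        base = predict_creatinine_tanaka(participant(age=50)).prcr_mg_day
        older = predict_creatinine_tanaka(participant(age=51)).prcr_mg_day
        assert base - older == pytest.approx(2.04)

    def test_sex_independent(self):
        f = predict_creatinine_tanaka(participant(sex="female")).prcr_mg_day
        m = predict_creatinine_tanaka(participant(sex="male")).prcr_mg_day
        assert f == m

    def test_implausible_inputs_flagged(self):
        # inputs far outside the adult calibration range drive the linear
        # form negative; this must be flagged, not clamped
        with pytest.raises(ImplausibleInputError):
            predict_creatinine_tanaka(participant(age=90, weight=36, height=90))


class TestKawasaki:
    def test_longhand_examples(self):
        m = predict_creatinine_kawasaki(participant(sex="male", age=50, weight=70, height=175))
        assert m.prcr_mg_day == pytest.approx(2903.25)
        f = predict_creatinine_kawasaki(participant(sex="female", age=50, weight=70, height=160))
        assert f.prcr_mg_day == pytest.approx(1104.5)

    @given(age=ages, weight=weights, height=heights)
    def test_male_exceeds_female_everywhere(self, age, weight, height):
        male = kawasaki_creatinine(age, weight, height, female=False)
        female = kawasaki_creatinine(age, weight, height, female=True)
        assert male > female

    def test_missing_sex_rejected(self):
        with pytest.raises(InputError):
            Participant(id="p", sex=None, age=50, weight=70, height=165)


class TestMage:
    def test_male_no_race_term(self):
        p = participant(sex="male", age=25, weight=70, height=175, ethnicity_black=0)
        got = predict_creatinine_mage(p).prcr_mg_day
        assert got == pytest.approx(mage_oracle(25, 70, 175, p.bmi, 0, False), rel=1e-12)
        assert got == pytest.approx(1595, abs=1)

    def test_female_with_race_term(self):
        p = participant(sex="female", age=52, weight=75, height=160, ethnicity_black=1)
        got = predict_creatinine_mage(p).prcr_mg_day
        assert got == pytest.approx(mage_oracle(52, 75, 160, p.bmi, 1, True), rel=1e-12)

    def test_race_term_vanishes_at_bracket_root(self):
        # men's bracket (1.366 - 0.0159*BMI) is zero at BMI = 1.366/0.0159
        bmi = 1.366 / 0.0159
        a0 = mage_creatinine(40, 80, 175, bmi, 0, False)
        a1 = mage_creatinine(40, 80, 175, bmi, 1, False)
        assert a0 == pytest.approx(a1, rel=1e-12)

    def test_missing_ethnicity_propagates_missing(self):
        assert predict_creatinine_mage(participant(ethnicity_black=None)) is None

    def test_age_domain(self):
        with pytest.raises(InputError):
            predict_creatinine_mage(
                Participant(id="p", sex="female", age=141, weight=70, height=165,
                            ethnicity_black=1)
            )


@given(age=ages, weight=weights, height=heights,
       female=st.booleans(), black=st.integers(0, 1))
def test_all_equations_positive_on_plausible_adults(age, weight, height, female, black):
    bmi = weight / (height / 100.0) ** 2
    assert tanaka_creatinine(age, weight, height) > 0
    assert kawasaki_creatinine(age, weight, height, female) > 0
    assert mage_creatinine(age, weight, height, bmi, black, female) > 0


class TestPredictUIE:
    def test_unit_cancellation(self):
        spot = SpotSample(uic=100.0, ucr_mg_dl=100.0)
        prcr = PredictedCreatinine(Equation.TANAKA, 1000.0)
        assert predict_uie(spot, prcr) == pytest.approx(100.0)

    def test_longhand(self):
        spot = SpotSample(uic=130.0, ucr_mg_dl=80.0)
        prcr = PredictedCreatinine(Equation.TANAKA, 1358.95)
        assert predict_uie(spot, prcr) == pytest.approx(220.829, abs=1e-3)

    @given(uic=st.floats(1, 500), ucr=st.floats(10, 400), prcr=st.floats(200, 4000))
    def test_linear_in_prcr_and_unit_invariant(self, uic, ucr, prcr):
        one = predicted_uie(uic, ucr, prcr)
        assert predicted_uie(uic, ucr, 2 * prcr) == pytest.approx(2 * one, rel=1e-12)
        # declaring the same concentration in mg/L after x10 changes nothing
        assert predicted_uie(uic, ucr * 10, prcr, ucr_unit="mg/L") == pytest.approx(
            one, rel=1e-12
        )

    def test_zero_creatinine_rejected(self):
        with pytest.raises(InputError):
            SpotSample(uic=100.0, ucr_mg_dl=0.0)


class TestMeasuredUIEAndIntake:
    def test_median_style_example(self):
        assert measured_uie(Urine24h(1400, 88.6, 10)) == pytest.approx(124.04)

    def test_one_litre_equivalence(self):
        # at exactly 1 L/day the concentration numerically equals the excretion
        assert measured_uie(Urine24h(1000, 173.4, 10)) == pytest.approx(173.4)

    def test_zero_volume(self):
        assert measured_uie(Urine24h(0, 500, 10)) == 0.0

    def test_bioavailability_division(self):
        assert intake_from_excretion(92.0) == pytest.approx(100.0)
        assert intake_from_excretion(0.0) == 0.0
        assert intake_from_excretion(124.0) == pytest.approx(134.78, abs=5e-3)
        with pytest.raises(InputError):
            intake_from_excretion(-1.0)

    @given(x=st.floats(0, 1e4))
    def test_intake_roundtrip_identity(self, x):
        assert intake_from_excretion(x * 0.92) == pytest.approx(x, rel=1e-12, abs=1e-12)


class TestIOMIntake:
    def test_longhand(self):
        assert iom_intake(130.0, 70.0) == pytest.approx(213.65, abs=5e-3)
        assert iom_intake(0.0, 70.0) == 0.0
        # weight chosen so the volume bracket is exactly 1 L/day
        assert iom_intake(92.0, 1000.0 / 21.6) == pytest.approx(100.0)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(InputError):
            iom_intake(100.0, 0.0)


class TestCompleteness:
    @pytest.mark.parametrize(
        "volume, creatinine, sex, complete",
        [
            (300.0, 10.0, "male", False),   # volume threshold is inclusive
            (301.0, 10.0, "male", True),
            (1400.0, 4.0, "female", False),  # women's creatinine floor inclusive
            (1400.0, 4.01, "female", True),
            (1400.0, 6.0, "male", False),
            (1400.0, 9.0, "male", True),
            (1400.0, 5.0, "female", True),   # 5 mmol passes for women only
            (1400.0, 5.0, "male", False),
        ],
    )
    def test_thresholds(self, volume, creatinine, sex, complete):
        u = Urine24h(volume, 100.0, creatinine)
        assert is_complete_collection(u, sex) is complete

    def test_missing_sex_rejected(self):
        with pytest.raises(InputError):
            is_complete_collection(Urine24h(1400, 100, 10), None)


class TestCreatinineUnits:
    def test_molar_mass(self):
        assert creatinine_mg_to_mmol(113.12) == pytest.approx(1.0)
        assert creatinine_mg_to_mmol(1131.2) == pytest.approx(10.0)

    @given(x=st.floats(0, 1e5))
    def test_roundtrip(self, x):
        assert creatinine_mmol_to_mg(creatinine_mg_to_mmol(x)) == pytest.approx(
            x, rel=1e-9, abs=1e-9
        )


def test_bmi_consistency_checked():
    with pytest.raises(InputError):
        participant(bmi=40.0)  # far from 70/(1.65^2) = 25.7
    p = participant(bmi=25.7)
    assert p.bmi == 25.7
    assert participant().bmi == pytest.approx(70.0 / 1.65**2)


def test_oracle_equivalence_on_random_plausible_inputs(rng):
    """All closed-form operations match the longhand oracles to 1e-9 relative."""
    for _ in range(100):
        age = rng.uniform(18, 90)
        weight = rng.uniform(40, 150)
        height = rng.uniform(140, 200)
        bmi = weight / (height / 100.0) ** 2
        black = int(rng.integers(0, 2))
        uic = rng.uniform(5, 500)
        ucr = rng.uniform(20, 300)

        assert tanaka_creatinine(age, weight, height) == pytest.approx(
            tanaka_oracle(age, weight, height), rel=1e-9)
        assert kawasaki_creatinine(age, weight, height, False) == pytest.approx(
            kawasaki_male_oracle(age, weight, height), rel=1e-9)
        assert kawasaki_creatinine(age, weight, height, True) == pytest.approx(
            kawasaki_female_oracle(age, weight, height), rel=1e-9)
        for female in (True, False):
            assert mage_creatinine(age, weight, height, bmi, black, female) == pytest.approx(
                mage_oracle(age, weight, height, bmi, black, female), rel=1e-9)
        prcr = tanaka_oracle(age, weight, height)
        if prcr > 0:
            assert predicted_uie(uic, ucr, prcr) == pytest.approx(
                pruie_oracle(uic, ucr, prcr), rel=1e-9)
        assert iom_intake(uic, weight) == pytest.approx(
            iom_intake_oracle(uic, weight), rel=1e-9)
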