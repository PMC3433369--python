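"""Unit and property tests for the risk-equation module."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chdval import risk_equations as rq
from chdval.errors import InvalidInputError

from conftest import random_profiles
from oracles import (fram_initial_risk_literal, fram_secondary_risk_literal,
                     ukpds_risk_literal)

REF_MALE = rq.PatientProfile(age=55, sex="male", hba1c=6.72, sbp=135.7,
                             total_cholesterol=math.exp(1.59) * 45, hdl=45)


class TestBPCategory:
    @pytest.mark.parametrize("sbp,dbp,expected", [
        (110, 70, "optimal"),
        (119.9, 79.9, "optimal"),
        (120, 70, "normal"),
        (110, 84, "normal"),
        (135, 70, "high_normal"),     # higher category (SBP) wins
        (110, 86, "high_normal"),
        (145, 70, "stage1"),
        (125, 95, "stage1"),
        (160, 70, "stage2_4"),
        (125, 102, "stage2_4"),       # DBP drives the category up
    ])
    def test_thresholds_and_higher_category_wins(self, sbp, dbp, expected):
        assert rq.bp_category(sbp, dbp) == expected

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(InvalidInputError):
            rq.bp_category(0, 80)


class TestUkpds:
    def test_reference_q(self):
        # reference profile zeroes every centred term: q = exp(-4.4918)
        assert rq.ukpds_q(REF_MALE)[0] == pytest.approx(math.exp(-4.4918), rel=1e-12)

    def test_single_term_multipliers(self):
        q0 = rq.ukpds_q(REF_MALE)[0]
        female = rq.PatientProfile(**{**REF_MALE.__dict__, "sex": "female"})
        black = rq.PatientProfile(**{**REF_MALE.__dict__, "afro_caribbean": 1})
        assert rq.ukpds_q(female)[0] == pytest.approx(q0 * math.exp(-0.6444), rel=1e-12)
        assert rq.ukpds_q(black)[0] == pytest.approx(q0 * math.exp(-0.9416), rel=1e-12)

    def test_incident_risk_values(self):
        q = rq.ukpds_q(REF_MALE)[0]
        assert rq.ukpds_incident_risk(REF_MALE, 0)[0] == 0.0
        assert rq.ukpds_incident_risk(REF_MALE, 1)[0] == pytest.approx(
            1 - math.exp(-q), rel=1e-12)
        assert rq.ukpds_incident_risk(REF_MALE, 10)[0] == pytest.approx(0.148, abs=5e-4)

    def test_duration_form_reduces_to_incident_at_T0(self, rng):
        cohort = random_profiles(rng, 300).assign(diabetes_duration=0.0)
        np.testing.assert_array_equal(rq.ukpds_duration_risk(cohort, 3.5),
                                      rq.ukpds_incident_risk(cohort, 3.5))

    def test_duration_scales_q_by_d_power_T(self):
        p10 = rq.PatientProfile(**{**REF_MALE.__dict__, "diabetes_duration": 10.0})
        r = rq.ukpds_duration_risk(p10, 1)[0]
        q_scaled = rq.ukpds_q(REF_MALE)[0] * 1.078 ** 10
        assert 1.078 ** 10 == pytest.approx(2.119, abs=5e-4)
        assert r == pytest.approx(1 - math.exp(-q_scaled), rel=1e-12)

    def test_duration_monotone_in_T(self, rng):
        cohort = random_profiles(rng, 100)
        r10 = rq.ukpds_duration_risk(cohort.assign(diabetes_duration=10.0), 3.5)
        r20 = rq.ukpds_duration_risk(cohort.assign(diabetes_duration=20.0), 3.5)
        assert (r20 >= r10).all()

    def test_negative_horizon_rejected(self):
        with pytest.raises(InvalidInputError):
            rq.ukpds_incident_risk(REF_MALE, -1)


class TestFraminghamInitial:
    def test_intercept_only_linear_predictor(self):
        # all reference categories; age term isolated by subtraction
        p = rq.PatientProfile(age=50, sex="male", total_cholesterol=180, hdl=47,
                              sbp=125, dbp=82, diabetes=0, smoker=0)
        m = rq.framingham_initial_lp(p)[0]
        assert m == pytest.approx(-3.0975 + 0.0483 * 50, rel=1e-12)

    def test_female_age_is_quadratic(self):
        base = dict(sex="female", total_cholesterol=180, hdl=52, sbp=125, dbp=82,
                    diabetes=0, smoker=0)
        m60 = rq.framingham_initial_lp(rq.PatientProfile(age=60, **base))[0]
        m40 = rq.framingham_initial_lp(rq.PatientProfile(age=40, **base))[0]
        expected = 0.3377 * (60 - 40) - 0.0027 * (60 ** 2 - 40 ** 2)
        assert m60 - m40 == pytest.approx(expected, rel=1e-12)

    def test_male_diabetes_and_smoker_increments(self):
        base = dict(age=50, sex="male", total_cholesterol=180, hdl=47, sbp=125, dbp=82)
        m00 = rq.framingham_initial_lp(rq.PatientProfile(**base, diabetes=0, smoker=0))[0]
        m10 = rq.framingham_initial_lp(rq.PatientProfile(**base, diabetes=1, smoker=0))[0]
        m11 = rq.framingham_initial_lp(rq.PatientProfile(**base, diabetes=1, smoker=1))[0]
        assert m10 - m00 == pytest.approx(0.4284, rel=1e-12)
        assert m11 - m10 == pytest.approx(0.5234, rel=1e-12)

    @pytest.mark.parametrize("sex,t,s0", [
        ("male", 1, 0.9946), ("male", 2, 0.9850), ("male", 5, 0.95592),
        ("female", 1, 0.9984), ("female", 5, 0.98297),
    ])
    def test_baseline_survival_anchor(self, sex, t, s0):
        assert rq.framingham_initial_risk(np.array([0.0]), sex, t)[0] == \
            pytest.approx(1 - s0, rel=1e-12)

    def test_extreme_negative_lp_gives_zero_risk(self):
        assert rq.framingham_initial_risk(np.array([-50.0]), "male", 5)[0] == \
            pytest.approx(0.0, abs=1e-15)

    def test_fractional_horizon_requires_interpolation(self):
        with pytest.raises(InvalidInputError):
            rq.framingham_initial_risk(np.array([0.0]), "male", 3.5)
        r3 = rq.framingham_initial_risk(np.array([0.0]), "male", 3, interpolate=True)[0]
        r35 = rq.framingham_initial_risk(np.array([0.0]), "male", 3.5, interpolate=True)[0]
        r4 = rq.framingham_initial_risk(np.array([0.0]), "male", 4, interpolate=True)[0]
        assert r3 < r35 < r4

    def test_risk_constant_within_categories(self, rng):
        # any profile change within the same TC/HDL/BP category is invisible
        base = random_profiles(rng, 50)
        jitter = base.copy()
        jitter["total_cholesterol"] = np.clip(base["total_cholesterol"] + 3, None, None)
        same_cat = (rq.tc_category(jitter["total_cholesterol"].to_numpy())
                    == rq.tc_category(base["total_cholesterol"].to_numpy()))
        m_base = rq.framingham_initial_lp(base)
        m_jit = rq.framingham_initial_lp(jitter)
        assert np.array_equal(m_base[same_cat], m_jit[same_cat])


class TestFraminghamSecondary:
    def test_risk_at_m_equal_ln_t(self):
        # choose age so that m = ln(t); then risk = 1 - exp(-1)
        t = 2.0
        c = rq.load_constants()["framingham_secondary"]["male"]
        tc_over_hdl = math.exp(1.0)
        age = (c["intercept"] + c["ln_tc_hdl"] * 1.0 + c["diabetes"] - math.log(t)) / (-c["age"])
        p = rq.PatientProfile(age=age, sex="male", total_cholesterol=tc_over_hdl * 45,
                              hdl=45, diabetes=1)
        assert rq.framingham_secondary_risk(p, t)[0] == pytest.approx(
            1 - math.exp(-1), rel=1e-9)

    def test_risk_vanishes_as_t_to_zero(self):
        p = rq.PatientProfile(age=65, sex="female", total_cholesterol=190, hdl=45)
        assert rq.framingham_secondary_risk(p, 1e-12)[0] < 1e-6

    def test_male_diabetes_raises_risk(self):
        base = dict(age=65, sex="male", total_cholesterol=190, hdl=45)
        r0 = rq.framingham_secondary_risk(rq.PatientProfile(**base, diabetes=0), 3.5)[0]
        r1 = rq.framingham_secondary_risk(rq.PatientProfile(**base, diabetes=1), 3.5)[0]
        assert r1 > r0

    def test_nonpositive_horizon_rejected(self):
        p = rq.PatientProfile(age=65, sex="male", total_cholesterol=190, hdl=45)
        with pytest.raises(InvalidInputError):
            rq.framingham_secondary_risk(p, 0.0)


class TestAgainstLiteralOracle:
    """Term-by-term transcriptions must agree with the vectorised path."""

    def test_all_equations_on_1000_random_profiles(self, rng):
        cohort = random_profiles(rng, 1000)
        t = 3.0
        got_u = rq.ukpds_duration_risk(cohort, t)
        got_f = rq.predicted_risk("fram_initial", cohort, t)
        got_s = rq.framingham_secondary_risk(cohort, t)
        for i, row in cohort.iterrows():
            female = row["sex"] == "female"
            exp_u = ukpds_risk_literal(row.age, female, row.afro_caribbean,
                                       row.smoker, row.hba1c, row.sbp,
                                       row.total_cholesterol, row.hdl,
                                       row.diabetes_duration, t)
            assert abs(got_u[i] - exp_u) < 1e-12
            exp_f = fram_initial_risk_literal(row["sex"], row.age,
                                              row.total_cholesterol, row.hdl,
                                              row.sbp, row.dbp, 1, row.smoker, t)
            assert abs(got_f[i] - exp_f) < 1e-12
            exp_s = fram_secondary_risk_literal(row["sex"], row.age,
                                                row.total_cholesterol, row.hdl,
                                                row.sbp, 1, row.smoker, t)
            assert abs(got_s[i] - exp_s) < 1e-12


class TestImpliedHazardRatio:
    def test_zero_coefficient_gives_unity(self):
        assert rq.implied_hazard_ratio("fram_secondary", "ln_sbp", sex="male") == 1.0
        assert rq.implied_hazard_ratio("fram_secondary", "smoker", sex="male") == 1.0

    def test_unknown_covariate_raises_lookup_error(self):
        with pytest.raises(KeyError):
            rq.implied_hazard_ratio("ukpds_incident", "bmi")

    def test_delta_scaling(self):
        hr1 = rq.implied_hazard_ratio("ukpds_incident", "age", 1)
        hr10 = rq.implied_hazard_ratio("ukpds_incident", "age", 10)
        assert hr10 == pytest.approx(hr1 ** 10, rel=1e-12)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(age=st.floats(18, 95), hba1c=st.floats(4, 14), sbp=st.floats(90, 210),
       tc=st.floats(100, 350), hdl=st.floats(20, 100), T=st.floats(0, 35),
       t1=st.floats(0.1, 10), t2=st.floats(0.1, 10),
       female=st.booleans(), smoker=st.booleans())
def test_risk_bounds_and_monotonicity_in_horizon(age, hba1c, sbp, tc, hdl, T,
                                                 t1, t2, female, smoker):
    """Every equation maps to [0,1] and is strictly increasing in t."""
    p = rq.PatientProfile(age=age, sex="female" if female else "male",
                          smoker=int(smoker), hba1c=hba1c, sbp=sbp,
                          total_cholesterol=tc, hdl=hdl, diabetes_duration=T)
    lo, hi = sorted((t1, t2))
    for fn in (rq.ukpds_incident_risk, rq.ukpds_duration_risk,
               rq.framingham_secondary_risk):
        r_lo, r_hi = fn(p, lo)[0], fn(p, hi)[0]
        assert 0.0 <= r_lo <= r_hi <= 1.0
        if hi > lo:
            assert r_hi > r_lo


def test_score_cohort_long_format(rng):
    cohort = random_profiles(rng, 20)
    table = rq.score_cohort(cohort, ["ukpds_incident", "fram_secondary"], [1.0, 3.5])
    assert len(table) == 20 * 2 * 2
    assert set(table.columns) == {"subject_id", "equation_id", "t", "probability"}
    assert table["probability"].between(0, 1).all()


def test_profile_invariants_enforced():
    with pytest.raises(InvalidInputError):
        rq.PatientProfile(age=17, sex="male")
    with pytest.raises(InvalidInputError):
        rq.PatientProfile(age=50, sex="male", hdl=0.0)
    with pytest.raises(InvalidInputError):
        rq.PatientProfile(age=50, sex="x")
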