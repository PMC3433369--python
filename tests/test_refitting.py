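"""Tests for Cox refitting, HR comparison and the group-based GOF test."""

import numpy as np
import pandas as pd
import pytest

from chdval import refitting as rf
from chdval import synthetic_cohort as sc
from chdval.errors import DegenerateGroupingError, InvalidInputError
from chdval.evaluation import harrell_c_index

from oracles import efron_loglik_direct


def _ph_data(rng, n, beta=(0.5, -0.3), censor_scale=4.0):
    X = rng.standard_normal((n, len(beta)))
    T = rng.exponential(3.0, n) * np.exp(-(X @ np.asarray(beta)))
    C = np.minimum(3.5, rng.exponential(censor_scale, n))
    t = np.minimum(T, C)
    e = (T <= C).astype(int)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(len(beta))])
    df["t"], df["e"] = t, e
    return df


class TestEfronLoglik:
    def test_matches_independent_transcription_and_derivatives(self, rng):
        """Analytic value/gradient/Hessian vs a direct transcription and
        central finite differences, on tied data."""
        n, p = 40, 3
        X = rng.standard_normal((n, p))
        times = rng.integers(1, 6, n).astype(float)
        events = rng.integers(0, 2, n)
        beta = rng.standard_normal(p) * 0.4
        ll, grad, hess = rf.efron_loglik(X, times, events, beta)
        assert ll == pytest.approx(efron_loglik_direct(X, times, events, beta),
                                   rel=1e-12)
        eps = 1e-6
        for i in range(p):
            d = eps * np.eye(p)[i]
            num = (efron_loglik_direct(X, times, events, beta + d)
                   - efron_loglik_direct(X, times, events, beta - d)) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-6)
            gp = rf.efron_loglik(X, times, events, beta + d)[1]
            gm = rf.efron_loglik(X, times, events, beta - d)[1]
            np.testing.assert_allclose(hess[i], (gp - gm) / (2 * eps), atol=1e-6)

    def test_translation_invariance_of_covariates(self, rng):
        """Adding a constant to a covariate leaves the partial likelihood
        shape (gradient at the optimum, Hessian) unchanged."""
        df = _ph_data(rng, 400)
        fit1 = rf.fit_cox(df, ["x0", "x1"], "t", "e", gof=False)
        shifted = df.assign(x0=df["x0"] + 100.0)
        fit2 = rf.fit_cox(shifted, ["x0", "x1"], "t", "e", gof=False)
        np.testing.assert_allclose(fit1.coef, fit2.coef, atol=1e-6)


class TestFitCox:
    def test_parameter_recovery(self, rng):
        df = _ph_data(rng, 10000)
        fit = rf.fit_cox(df, ["x0", "x1"], "t", "e", gof=False)
        assert fit.coef[0] == pytest.approx(0.5, abs=0.05)
        assert fit.coef[1] == pytest.approx(-0.3, abs=0.05)
        assert (fit.se > 0).all()

    def test_hr_is_exp_coef_exactly(self, rng):
        df = _ph_data(rng, 500)
        fit = rf.fit_cox(df, ["x0", "x1"], "t", "e", gof=False)
        np.testing.assert_array_equal(fit.hr, np.exp(fit.coef))

    def test_c_index_consistent_with_harrell(self, rng):
        df = _ph_data(rng, 400)
        fit = rf.fit_cox(df, ["x0", "x1"], "t", "e", gof=False)
        lp = df[["x0", "x1"]].to_numpy() @ fit.coef
        c = harrell_c_index(lp, df["t"].to_numpy(), df["e"].to_numpy(),
                            ci_method="noether")
        assert fit.c_index == pytest.approx(c.c_index, abs=1e-12)

    def test_collinear_design_rejected(self, rng):
        df = _ph_data(rng, 200)
        df["x2"] = 2 * df["x0"]
        with pytest.raises(np.linalg.LinAlgError):
            rf.fit_cox(df, ["x0", "x1", "x2"], "t", "e")

    def test_too_few_events_rejected(self, rng):
        df = _ph_data(rng, 50)
        df["e"] = 0
        with pytest.raises(InvalidInputError):
            rf.fit_cox(df, ["x0", "x1"], "t", "e")


class TestCoxGof:
    def test_matches_score_test_oracle_small_n(self, rng):
        """Score statistic vs explicit finite-difference matrix algebra."""
        df = _ph_data(rng, 60, beta=(0.4,))
        X = df[["x0"]].to_numpy()
        t, e = df["t"].to_numpy(), df["e"].to_numpy()
        fit = rf.fit_cox(df, ["x0"], "t", "e", G=3)
        beta_hat = rf._newton_refine(X, t, e, fit.coef)
        lp = X @ beta_hat
        groups = pd.qcut(pd.Series(lp).rank(method="first"), q=3, labels=False)
        dummies = np.column_stack([(groups == g).astype(float) for g in (1, 2)])
        X_ext = np.column_stack([X, dummies])
        theta = np.concatenate([beta_hat, [0.0, 0.0]])
        # finite-difference score and information of the extended model
        eps = 1e-5
        k = X_ext.shape[1]
        U = np.zeros(k)
        for i in range(k):
            d = eps * np.eye(k)[i]
            U[i] = (efron_loglik_direct(X_ext, t, e, theta + d)
                    - efron_loglik_direct(X_ext, t, e, theta - d)) / (2 * eps)
        info = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                di, dj = eps * np.eye(k)[i], eps * np.eye(k)[j]
                info[i, j] = -(efron_loglik_direct(X_ext, t, e, theta + di + dj)
                               - efron_loglik_direct(X_ext, t, e, theta + di - dj)
                               - efron_loglik_direct(X_ext, t, e, theta - di + dj)
                               + efron_loglik_direct(X_ext, t, e, theta - di - dj)
                               ) / (4 * eps ** 2)
        V = info[1:, 1:] - info[1:, :1] @ np.linalg.solve(info[:1, :1], info[:1, 1:])
        expected = float(U[1:] @ np.linalg.solve(V, U[1:]))
        stat, dof, p = rf.cox_gof(X, t, e, fit.coef, G=3)
        assert dof == 2
        assert stat == pytest.approx(expected, rel=1e-3, abs=1e-4)

    def test_statistic_nonnegative(self, rng):
        for _ in range(5):
            df = _ph_data(rng, 300, beta=(0.6,))
            stat, _, p = rf.cox_gof(df[["x0"]].to_numpy(), df["t"].to_numpy(),
                                    df["e"].to_numpy(), [0.6], G=5)
            assert stat >= 0 and 0 <= p <= 1

    def test_null_rejection_rate(self, rng):
        """Correctly specified model: ~5% rejections at the 0.05 level."""
        rejections = 0
        n_reps = 200
        for _ in range(n_reps):
            df = _ph_data(rng, 400, beta=(0.5,), censor_scale=10.0)
            fit = rf.fit_cox(df, ["x0"], "t", "e", G=5, gof=False)
            _, _, p = rf.cox_gof(df[["x0"]].to_numpy(), df["t"].to_numpy(),
                                 df["e"].to_numpy(), fit.coef, G=5)
            rejections += p < 0.05
        assert 0.015 <= rejections / n_reps <= 0.10

    def test_too_few_events_for_grouping(self, rng):
        df = _ph_data(rng, 40)
        df.loc[df.index[5:], "e"] = 0
        with pytest.raises(DegenerateGroupingError):
            rf.cox_gof(df[["x0", "x1"]].to_numpy(), df["t"].to_numpy(),
                       df["e"].to_numpy(), [0.1, 0.1], G=10)


class TestCompareHazardRatios:
    def test_identical_coefficients_give_zero_z(self):
        fit = rf.CoxFitResult(["a"], np.array([0.5]), np.array([0.1]),
                              np.eye(1) * 0.01, np.exp([0.5]), 0.0, 0.5,
                              0.0, 0, 1.0, 100, 20)
        out = rf.compare_hazard_ratios(fit, {"a": (0.5, 0.1)})
        assert out["z"][0] == 0.0 and out["p"][0] == 1.0

    def test_hand_z(self):
        fit = rf.CoxFitResult(["a"], np.array([0.3]), np.array([0.1]),
                              np.eye(1) * 0.01, np.exp([0.3]), 0.0, 0.5,
                              0.0, 0, 1.0, 100, 20)
        out = rf.compare_hazard_ratios(fit, {"a": (0.5, 0.1)})
        assert out["z"][0] == pytest.approx(-1.4142, abs=1e-4)
        assert not out["anticonservative"][0]

    def test_missing_original_se_flagged(self):
        fit = rf.CoxFitResult(["a"], np.array([0.3]), np.array([0.1]),
                              np.eye(1) * 0.01, np.exp([0.3]), 0.0, 0.5,
                              0.0, 0, 1.0, 100, 20)
        out = rf.compare_hazard_ratios(fit, {"a": (0.5, None)})
        assert out["anticonservative"][0]
        assert out["z"][0] == pytest.approx(-2.0)

    def test_name_mismatch_rejected(self):
        fit = rf.CoxFitResult(["a"], np.array([0.3]), np.array([0.1]),
                              np.eye(1) * 0.01, np.exp([0.3]), 0.0, 0.5,
                              0.0, 0, 1.0, 100, 20)
        with pytest.raises(InvalidInputError):
            rf.compare_hazard_ratios(fit, {"b": (0.5, 0.1)})


class TestEquationRefits:
    def test_ukpds_refits_differ_only_by_duration_term(self, small_cohort):
        d1 = rf.build_design(small_cohort, "ukpds_incident")
        d2 = rf.build_design(small_cohort, "ukpds_duration")
        assert list(d2.columns) == list(d1.columns) + ["diabetes_duration"]

    def test_refit_recovers_generating_coefficients(self):
        """Cohort simulated from the UKPDS engine: the refitted log-HRs
        approach the published ones (the truth), per-mmHg SBP included."""
        df = sc.generate_cohort(sc.CohortConfig(n=40000, seed=77))
        fit, comparison = rf.refit_equation(df, "ukpds_incident", "ukpds")
        orig = {k: v for k, (v, _) in
                rf.original_coefficients("ukpds_incident").items()}
        for name, b, se in zip(fit.names, fit.coef, fit.se):
            assert b == pytest.approx(orig[name], abs=4 * se + 0.02)
        assert comparison["anticonservative"].all()

    def test_secondary_design_is_reduced(self, secondary_cohort):
        males = secondary_cohort[secondary_cohort["sex"] == "male"]
        d = rf.build_design(males, "fram_secondary")
        assert list(d.columns) == ["age", "ln_tc_hdl"]
        females = secondary_cohort[secondary_cohort["sex"] == "female"]
        d = rf.build_design(females, "fram_secondary")
        assert list(d.columns) == ["age", "ln_tc_hdl", "ln_sbp", "smoker"]

    def test_fram_initial_design_requires_single_sex(self, small_cohort):
        with pytest.raises(InvalidInputError):
            rf.build_design(small_cohort, "fram_initial")
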