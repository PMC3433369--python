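"""Cox refits of the published risk-equation predictor sets.

To ask whether a published equation's covariate effects transfer to a new
cohort, each equation's predictor set is refitted as a Cox
proportional-hazards model on the cohort (same event definition, same
parameterisation: continuous HbA1c/SBP/ln(TC/HDL) plus indicators for the
UKPDS engine; lipid/blood-pressure category indicators for the
Framingham-initial set; the reduced secondary predictor sets).  Refitted
hazard ratios are compared to the published ones with the normal-deviate
test ``z = (b_new - b_orig) / sqrt(se_new^2 + se_orig^2)``; when the
original standard errors were never published the comparison uses
``se_new`` alone and is flagged anti-conservative.

Model fitting is delegated to lifelines (Efron tie handling).  The
goodness-of-fit test is a Grønnesby–Borgan-type score test implemented
here: indicators for prognostic-index risk groups are added to the fitted
model and their joint nullity is score-tested against chi-square with
G - 1 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from . import risk_equations as rq
from .errors import (ConvergenceError, DegenerateGroupingError,
                     InvalidInputError)
from .evaluation import concordance_counts


@dataclass
class CoxFitResult:
    names: list
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    hr: np.ndarray
    log_likelihood: float
    c_index: float
    gof_statistic: float
    gof_df: int
    gof_p: float
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        p = 2 * stats.norm.sf(np.abs(self.coef / self.se))
        return pd.DataFrame({"variable": self.names, "coef": self.coef,
                             "se": self.se, "p": p, "hr": self.hr})


# ---------------------------------------------------------------------------
# Efron partial likelihood (log-likelihood, score, information)
# ---------------------------------------------------------------------------

def efron_loglik(X: np.ndarray, times: np.ndarray, events: np.ndarray,
                 beta: np.ndarray):
    """Log partial likelihood with Efron tie correction, plus its gradient
    and Hessian at ``beta``.  O(n p^2) with a Python loop over distinct
    observed times; intended for desk-scale designs."""
    n, p = X.shape
    order = np.argsort(-times, kind="stable")
    Xs, ts, es = X[order], times[order], events[order]
    lp = Xs @ beta
    r = np.exp(lp)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        grp = slice(i, j)
        rg = r[grp]
        Xg = Xs[grp]
        S0 += rg.sum()
        S1 += rg @ Xg
        S2 += (rg[:, None] * Xg).T @ Xg
        ev = es[grp] == 1
        d = int(ev.sum())
        if d:
            rd = rg[ev]
            Xd = Xg[ev]
            ll += lp[grp][ev].sum()
            grad += Xd.sum(axis=0)
            S0D = rd.sum()
            S1D = rd @ Xd
            S2D = (rd[:, None] * Xd).T @ Xd
            for l in range(d):
                f = l / d
                den = S0 - f * S0D
                num = S1 - f * S1D
                ll -= math.log(den)
                grad -= num / den
                hess -= (S2 - f * S2D) / den - np.outer(num, num) / den ** 2
        i = j
    return ll, grad, hess


def _newton_refine(X, times, events, beta, gtol=1e-9, max_iter=25):
    beta = np.asarray(beta, dtype=float).copy()
    for _ in range(max_iter):
        ll, grad, hess = efron_loglik(X, times, events, beta)
        if np.linalg.norm(grad) < gtol:
            return beta
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information during Newton refinement") from exc
        beta = beta + step
    return beta


def cox_gof(X: np.ndarray, times, events, beta, G: int = 10) -> tuple:
    """Grønnesby–Borgan-type goodness-of-fit score test.

    Subjects are grouped by quantiles of the prognostic index X @ beta;
    G - 1 group indicators are added to the model and score-tested for
    joint nullity at the fitted coefficients.  Returns
    ``(statistic, df, p_value)``.
    """
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < G:
        raise DegenerateGroupingError(
            f"need at least G={G} events for a {G}-group test; lower G")
    lp = X @ np.asarray(beta, dtype=float)
    groups = pd.qcut(pd.Series(lp).rank(method="first"), q=G, labels=False)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise DegenerateGroupingError("prognostic index has no spread; cannot group")
    dummies = np.column_stack([(groups == g).astype(float) for g in labels[1:]])
    beta_hat = _newton_refine(X, times, events, beta)
    X_ext = np.column_stack([X, dummies])
    theta = np.concatenate([beta_hat, np.zeros(dummies.shape[1])])
    _, U, H = efron_loglik(X_ext, times, events, theta)
    info = -H
    p = X.shape[1]
    I_xx = info[:p, :p]
    I_gx = info[p:, :p]
    I_gg = info[p:, p:]
    V = I_gg - I_gx @ np.linalg.solve(I_xx, I_gx.T)
    Ug = U[p:]
    try:
        stat = float(Ug @ np.linalg.solve(V, Ug))
    except np.linalg.LinAlgError as exc:
        raise DegenerateGroupingError(
            "singular group information (a risk group may have no events); "
            "lower G") from exc
    df = dummies.shape[1]
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Cox fitting (lifelines) and HR comparison
# ---------------------------------------------------------------------------

def fit_cox(cohort: pd.DataFrame, covariates: list, duration_col: str,
            event_col: str, G: int = 10, gof: bool = True) -> CoxFitResult:
    """Fit a Cox PH model (Efron ties) and package coefficients, HRs,
    the c-index of the prognostic index, and the group-based GOF p-value."""
    events = np.asarray(cohort[event_col], dtype=int)
    if events.sum() < 2:
        raise InvalidInputError("need at least 2 events to fit a Cox model")
    X = cohort[covariates].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < len(covariates):
        raise np.linalg.LinAlgError(
            "design matrix is collinear (includes constant columns?); "
            "singular information")
    df = cohort[covariates + [duration_col, event_col]]
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    coef = cph.params_.reindex(covariates).to_numpy()
    se = cph.standard_errors_.reindex(covariates).to_numpy()
    cov = cph.variance_matrix_.reindex(index=covariates, columns=covariates).to_numpy()
    times = np.asarray(cohort[duration_col], dtype=float)
    lp = X @ coef
    conc, disc, tied = concordance_counts(lp, times, events)
    c_index = (conc + 0.5 * tied) / (conc + disc + tied)
    if gof:
        stat, dof, pval = cox_gof(X, times, events, coef, G=G)
    else:
        stat, dof, pval = math.nan, 0, math.nan
    return CoxFitResult(names=list(covariates), coef=coef, se=se, cov=cov,
                        hr=np.exp(coef), log_likelihood=float(cph.log_likelihood_),
                        c_index=float(c_index), gof_statistic=stat, gof_df=dof,
                        gof_p=pval, n=len(cohort), n_events=int(events.sum()))


def compare_hazard_ratios(fit: CoxFitResult, original: dict) -> pd.DataFrame:
    """Normal-deviate comparison of refitted vs published coefficients.

    ``original`` maps covariate name to ``(coef, se)``; pass ``se=None``
    when the source never published standard errors — the z then uses the
    refit SE alone and the row is flagged anti-conservative.
    """
    missing = [n for n in fit.names if n not in original]
    if missing:
        raise InvalidInputError(f"no original coefficients for: {missing}")
    rows = []
    for name, b_new, se_new in zip(fit.names, fit.coef, fit.se):
        b_orig, se_orig = original[name]
        flagged = se_orig is None
        denom = se_new if flagged else math.sqrt(se_new ** 2 + se_orig ** 2)
        z = (b_new - b_orig) / denom
        rows.append({"variable": name, "coef_new": b_new, "se_new": se_new,
                     "hr_new": math.exp(b_new), "coef_orig": b_orig,
                     "hr_orig": math.exp(b_orig), "z": z,
                     "p": 2 * stats.norm.sf(abs(z)),
                     "anticonservative": flagged})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Published predictor sets (the Table-4-style parameterisations)
# ---------------------------------------------------------------------------

def _indicator(series, category) -> np.ndarray:
    return (np.asarray(series, dtype=object) == category).astype(float)


def build_design(cohort: pd.DataFrame, equation_id: str) -> pd.DataFrame:
    """Design matrix with the same predictors as the named equation.

    Framingham designs are sex-specific: pass a single-sex cohort.
    """
    out = pd.DataFrame(index=cohort.index)
    if equation_id in ("ukpds_incident", "ukpds_duration"):
        out["age"] = cohort["age"].astype(float)
        out["female"] = (cohort["sex"] == "female").astype(float)
        out["afro_caribbean"] = cohort["afro_caribbean"].astype(float)
        out["smoker"] = cohort["smoker"].astype(float)
        out["hba1c"] = cohort["hba1c"].astype(float)
        out["sbp"] = cohort["sbp"].astype(float)
        out["ln_tc_hdl"] = np.log(cohort["total_cholesterol"] / cohort["hdl"])
        if equation_id == "ukpds_duration":
            out["diabetes_duration"] = cohort["diabetes_duration"].astype(float)
        return out
    sexes = set(cohort["sex"])
    if len(sexes) != 1:
        raise InvalidInputError(f"{equation_id} designs are sex-specific; "
                                "pass a single-sex cohort")
    sex = sexes.pop()
    if equation_id == "fram_initial":
        out["age"] = cohort["age"].astype(float)
        if sex == "female":
            out["age_squared"] = out["age"] ** 2
        tc_cat = rq.tc_category(np.asarray(cohort["total_cholesterol"], dtype=float))
        hdl_cat = rq.hdl_category(np.asarray(cohort["hdl"], dtype=float))
        bp_cat = rq.bp_category(np.asarray(cohort["sbp"], dtype=float),
                                np.asarray(cohort["dbp"], dtype=float))
        hdl_ref = "45_49" if sex == "male" else "50_59"
        for cat in rq.TC_CATEGORIES:
            if cat != "160_199":
                out[f"tc_{cat}"] = _indicator(tc_cat, cat)
        for cat in rq.HDL_CATEGORIES:
            if cat != hdl_ref:
                out[f"hdl_{cat}"] = _indicator(hdl_cat, cat)
        for cat in rq.BP_CATEGORIES:
            if cat != "normal":
                out[f"bp_{cat}"] = _indicator(bp_cat, cat)
        out["smoker"] = cohort["smoker"].astype(float)
        return out
    if equation_id == "fram_secondary":
        out["age"] = cohort["age"].astype(float)
        out["ln_tc_hdl"] = np.log(cohort["total_cholesterol"] / cohort["hdl"])
        if sex == "female":
            out["ln_sbp"] = np.log(cohort["sbp"].astype(float))
            out["smoker"] = cohort["smoker"].astype(float)
        return out
    raise InvalidInputError(f"unknown equation_id {equation_id!r}")


def original_coefficients(equation_id: str, sex: str | None = None) -> dict:
    """Published log-hazard-ratio coefficients aligned with build_design.

    Values are (coef, se); the published sources provide no SEs for these
    coefficient sets, so se is None throughout and comparisons are
    flagged anti-conservative.
    """
    c = rq.load_constants()
    if equation_id in ("ukpds_incident", "ukpds_duration"):
        u = c["ukpds"]["coefficients"]
        out = {"age": u["age"], "female": u["female"],
               "afro_caribbean": u["afro_caribbean"], "smoker": u["smoker"],
               "hba1c": u["hba1c"], "sbp": u["sbp_per_10mmhg"] / 10.0,
               "ln_tc_hdl": u["ln_tc_hdl"]}
        if equation_id == "ukpds_duration":
            out["diabetes_duration"] = math.log(c["ukpds"]["d"])
        return {k: (v, None) for k, v in out.items()}
    if sex not in ("male", "female"):
        raise InvalidInputError(f"{equation_id} is sex-specific; pass sex=")
    if equation_id == "fram_initial":
        f = c["framingham_initial"][sex]
        hdl_ref = "45_49" if sex == "male" else "50_59"
        out = {"age": f["age"], "smoker": f["smoker"]}
        if sex == "female":
            out["age_squared"] = f["age_squared"]
        for cat in rq.TC_CATEGORIES:
            if cat != "160_199":
                out[f"tc_{cat}"] = f["tc"][cat]
        for cat in rq.HDL_CATEGORIES:
            if cat != hdl_ref:
                out[f"hdl_{cat}"] = f["hdl"][cat]
        for cat in rq.BP_CATEGORIES:
            if cat != "normal":
                out[f"bp_{cat}"] = f["bp"][cat]
        return {k: (v, None) for k, v in out.items()}
    if equation_id == "fram_secondary":
        f = c["framingham_secondary"][sex]
        sigma = f["sigma"]
        out = {"age": -f["age"] / sigma, "ln_tc_hdl": -f["ln_tc_hdl"] / sigma}
        if sex == "female":
            out["ln_sbp"] = -f["ln_sbp"] / sigma
            out["smoker"] = -f["smoker"] / sigma
        return {k: (v, None) for k, v in out.items()}
    raise InvalidInputError(f"unknown equation_id {equation_id!r}")


def refit_equation(cohort: pd.DataFrame, equation_id: str,
                   event_definition: str, G: int = 10) -> tuple:
    """Refit one equation's predictor set on a cohort.

    Returns ``(CoxFitResult, comparison DataFrame)`` where the comparison
    tests each refitted HR against the published one.
    """
    design = build_design(cohort, equation_id)
    data = design.copy()
    data["_time"] = np.asarray(cohort[f"time_{event_definition}"], dtype=float)
    data["_event"] = np.asarray(cohort[f"event_{event_definition}"], dtype=int)
    fit = fit_cox(data, list(design.columns), "_time", "_event", G=G)
    sex = None
    if equation_id.startswith("fram"):
        sex = list(set(cohort["sex"]))[0]
    comparison = compare_hazard_ratios(fit, original_coefficients(equation_id, sex))
    return fit, comparison
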