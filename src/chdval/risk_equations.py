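"""Published CHD risk equations and quantities derived from them.

Implements four absolute-risk equations for coronary heart disease (CHD):

* ``ukpds_incident`` — risk of a first CHD event for a person with newly
  diagnosed type 2 diabetes.  The annual hazard ``q`` grows geometrically
  with attained diabetes duration through the ratio ``d``; the t-year risk
  is ``1 - exp(-q (1 - d^t) / (1 - d))``.
* ``ukpds_duration`` — the same engine, with the baseline hazard scaled by
  ``d^T`` for a person who already has ``T`` years of diabetes duration.
* ``fram_initial`` — sex-specific proportional-hazards form
  ``1 - S0(t)^exp(m)`` built on total-cholesterol, HDL and blood-pressure
  categories, with printed baseline survivals ``S0(1..5)``.
* ``fram_secondary`` — sex-specific accelerated-failure-time (log-Weibull)
  form ``1 - exp(-exp((ln t - m) / sigma))`` for people with established
  CHD.

All coefficient values live in ``equation_constants.json`` (shipped with
the package, versioned, immutable once loaded).  Every scoring function is
vectorised over a cohort ``DataFrame``; the cohort column schema is
documented in :mod:`chdval.io`.

Units are fixed: lipids in mg/dL, pressures in mmHg, HbA1c in percent,
age and diabetes duration in years.  No unit auto-conversion is attempted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError

EQUATION_IDS = ("ukpds_incident", "ukpds_duration", "fram_initial", "fram_secondary")

BP_CATEGORIES = ("optimal", "normal", "high_normal", "stage1", "stage2_4")
TC_CATEGORIES = ("lt160", "160_199", "200_239", "240_279", "ge280")
HDL_CATEGORIES = ("lt35", "35_44", "45_49", "50_59", "ge60")


@lru_cache(maxsize=1)
def load_constants() -> Mapping:
    """Load the equation-constant file shipped with the package.

    The returned mapping is cached and must be treated as read-only.
    """
    with resources.files("chdval").joinpath("equation_constants.json").open() as fh:
        return json.load(fh)


def constants_version() -> str:
    return load_constants()["version"]


@dataclass(frozen=True)
class PatientProfile:
    """Baseline covariates for one subject.

    ``diabetes`` defaults to 1: every subject in the population these
    equations are validated on has type 2 diabetes.  The indicator is
    configurable so the Framingham terms can be exercised in isolation.
    """

    age: float
    sex: str  # "male" or "female"
    afro_caribbean: int = 0
    smoker: int = 0
    hba1c: float = 7.0
    sbp: float = 130.0
    dbp: float = 80.0
    total_cholesterol: float = 200.0
    hdl: float = 45.0
    diabetes_duration: float = 0.0
    diabetes: int = 1
    chd_history: int = 0

    def __post_init__(self):
        if self.age < 18:
            raise InvalidInputError(f"age must be >= 18, got {self.age}")
        if self.sex not in ("male", "female"):
            raise InvalidInputError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.hdl <= 0 or self.total_cholesterol <= 0:
            raise InvalidInputError("hdl and total_cholesterol must be positive "
                                    "(log(TC/HDL) must be defined)")
        if self.sbp <= 0 or self.dbp <= 0:
            raise InvalidInputError("blood pressures must be positive")
        if self.diabetes_duration < 0:
            raise InvalidInputError("diabetes_duration must be >= 0")
        for name in ("afro_caribbean", "smoker", "diabetes", "chd_history"):
            if getattr(self, name) not in (0, 1):
                raise InvalidInputError(f"{name} must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass(frozen=True)
class RiskPrediction:
    """One equation's predicted probability for one subject and horizon."""

    equation_id: str
    horizon_t: float
    probability: float


def _as_cohort(profile) -> pd.DataFrame:
    if isinstance(profile, PatientProfile):
        return profile.to_frame()
    return profile


def _col(df: pd.DataFrame, name: str) -> np.ndarray:
    if name not in df.columns:
        raise InvalidInputError(f"cohort table lacks required column {name!r}")
    return np.asarray(df[name], dtype=float if name != "sex" else object)


def _female(df: pd.DataFrame) -> np.ndarray:
    sex = np.asarray(df["sex"], dtype=object)
    bad = ~np.isin(sex, ("male", "female"))
    if bad.any():
        raise InvalidInputError(f"sex must be 'male'/'female'; offending values "
                                f"{set(sex[bad])}")
    return (sex == "female").astype(float)


# ---------------------------------------------------------------------------
# Category definitions (JNC-style blood-pressure stages; Framingham lipid cuts)
# ---------------------------------------------------------------------------

def bp_category(sbp, dbp):
    """JNC-style blood-pressure category used by the Framingham-initial model.

    optimal  SBP < 120 and DBP < 80
    normal   SBP 120-129 or DBP 80-84
    high_normal SBP 130-139 or DBP 85-89
    stage1   SBP 140-159 or DBP 90-99
    stage2_4 SBP >= 160 or DBP >= 100

    When SBP and DBP fall in different categories the higher one wins.
    Accepts scalars or arrays; returns a scalar string or object array.
    """
    sbp_a = np.atleast_1d(np.asarray(sbp, dtype=float))
    dbp_a = np.atleast_1d(np.asarray(dbp, dtype=float))
    if (sbp_a <= 0).any() or (dbp_a <= 0).any():
        raise InvalidInputError("blood pressures must be positive")
    s_idx = np.searchsorted([120, 130, 140, 160], sbp_a, side="right")
    d_idx = np.searchsorted([80, 85, 90, 100], dbp_a, side="right")
    idx = np.maximum(s_idx, d_idx)
    out = np.asarray(BP_CATEGORIES, dtype=object)[idx]
    if np.isscalar(sbp) and np.isscalar(dbp):
        return out[0]
    return out


def tc_category(tc):
    tc_a = np.atleast_1d(np.asarray(tc, dtype=float))
    if (tc_a <= 0).any():
        raise InvalidInputError("total cholesterol must be positive")
    idx = np.searchsorted([160, 200, 240, 280], tc_a, side="right")
    out = np.asarray(TC_CATEGORIES, dtype=object)[idx]
    return out[0] if np.isscalar(tc) else out


def hdl_category(hdl):
    hdl_a = np.atleast_1d(np.asarray(hdl, dtype=float))
    if (hdl_a <= 0).any():
        raise InvalidInputError("HDL must be positive")
    idx = np.searchsorted([35, 45, 50, 60], hdl_a, side="right")
    out = np.asarray(HDL_CATEGORIES, dtype=object)[idx]
    return out[0] if np.isscalar(hdl) else out


# ---------------------------------------------------------------------------
# UKPDS risk engine
# ---------------------------------------------------------------------------

def ukpds_q(profile) -> np.ndarray:
    """Annual hazard ``q`` of the UKPDS engine for each subject.

    ``log q`` is linear in age (centred at 55), female sex, Afro-Caribbean
    ethnicity, smoking, HbA1c (centred at 6.72%), SBP per 10 mmHg (centred
    at 135.7 mmHg), and ln(TC/HDL) (centred at 1.59).
    """
    df = _as_cohort(profile)
    c = load_constants()["ukpds"]
    beta = c["coefficients"]
    ctr = c["centers"]
    hdl = _col(df, "hdl")
    tc = _col(df, "total_cholesterol")
    if (hdl <= 0).any() or (tc <= 0).any():
        raise InvalidInputError("hdl and total_cholesterol must be positive")
    log_q = (
        c["log_q_intercept"]
        + beta["age"] * (_col(df, "age") - ctr["age"])
        + beta["female"] * _female(df)
        + beta["afro_caribbean"] * _col(df, "afro_caribbean")
        + beta["smoker"] * _col(df, "smoker")
        + beta["hba1c"] * (_col(df, "hba1c") - ctr["hba1c"])
        + beta["sbp_per_10mmhg"] * (_col(df, "sbp") - ctr["sbp"]) / 10.0
        + beta["ln_tc_hdl"] * (np.log(tc / hdl) - ctr["ln_tc_hdl"])
    )
    return np.exp(log_q)


def _ukpds_time_factor(t, d: float):
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise InvalidInputError("horizon t must be >= 0")
    # (1 - d^t)/(1 - d) written for d > 1; equals t in the limit d -> 1
    return (np.power(d, t) - 1.0) / (d - 1.0)


def ukpds_incident_risk(profile, t) -> np.ndarray:
    """t-year first-CHD-event risk for newly diagnosed diabetes."""
    df = _as_cohort(profile)
    d = load_constants()["ukpds"]["d"]
    q = ukpds_q(df)
    return 1.0 - np.exp(-q * _ukpds_time_factor(t, d))


def ukpds_duration_risk(profile, t) -> np.ndarray:
    """t-year risk accounting for attained diabetes duration ``T``.

    The annual hazard is ``q * d^T``; with ``T = 0`` this reduces exactly
    to :func:`ukpds_incident_risk`.
    """
    df = _as_cohort(profile)
    d = load_constants()["ukpds"]["d"]
    T = _col(df, "diabetes_duration")
    if (T < 0).any():
        raise InvalidInputError("diabetes_duration must be >= 0")
    q = ukpds_q(df) * np.power(d, T)
    return 1.0 - np.exp(-q * _ukpds_time_factor(t, d))


# ---------------------------------------------------------------------------
# Framingham-initial (category-based proportional-hazards form)
# ---------------------------------------------------------------------------

def _category_score(values, categories: Sequence[str], coef_table: Mapping[str, float]):
    mapping = {c: coef_table[c] for c in categories}
    return np.array([mapping[v] for v in values], dtype=float)


def framingham_initial_lp(profile) -> np.ndarray:
    """Sex-specific linear predictor ``m`` (intercept included).

    Reference categories (TC 160-199, BP normal, and the sex-specific HDL
    reference: 45-49 for men, 50-59 for women) contribute zero.
    """
    df = _as_cohort(profile)
    female = _female(df).astype(bool)
    age = _col(df, "age")
    tc_cat = tc_category(np.atleast_1d(_col(df, "total_cholesterol")))
    hdl_cat = hdl_category(np.atleast_1d(_col(df, "hdl")))
    bp_cat = bp_category(np.atleast_1d(_col(df, "sbp")), np.atleast_1d(_col(df, "dbp")))
    smoker = _col(df, "smoker")
    diabetes = _col(df, "diabetes") if "diabetes" in df.columns else np.ones(len(df))

    consts = load_constants()["framingham_initial"]
    m = np.empty(len(df), dtype=float)
    for sex_key, mask in (("male", ~female), ("female", female)):
        if not mask.any():
            continue
        c = consts[sex_key]
        m[mask] = (
            c["intercept"]
            + c["age"] * age[mask]
            + c["age_squared"] * age[mask] ** 2
            + _category_score(tc_cat[mask], TC_CATEGORIES, c["tc"])
            + _category_score(hdl_cat[mask], HDL_CATEGORIES, c["hdl"])
            + _category_score(bp_cat[mask], BP_CATEGORIES, c["bp"])
            + c["diabetes"] * diabetes[mask]
            + c["smoker"] * smoker[mask]
        )
    return m


def _baseline_cumhaz(sex_key: str, t: float, interpolate: bool) -> float:
    """Baseline cumulative hazard -ln S0(t) of the Framingham-initial model.

    Printed anchors exist only at integer t in 1..5.  With
    ``interpolate=True``, ln(-ln S0) is interpolated linearly in t between
    the anchors, and for t < 1 the cumulative hazard is scaled linearly
    from the t=1 anchor.
    """
    s0 = load_constants()["framingham_initial"][sex_key]["baseline_survival"]
    if t == 0:
        return 0.0
    if not interpolate:
        if float(t).is_integer() and 1 <= int(t) <= 5:
            return -math.log(s0[str(int(t))])
        raise InvalidInputError(
            f"Framingham-initial horizon must be an integer in 1..5 "
            f"(got {t}); pass interpolate=True for fractional horizons")
    if t < 0 or t > 5:
        raise InvalidInputError(f"horizon {t} outside the supported range (0, 5]")
    knots_t = np.arange(1.0, 6.0)
    knots_h = np.array([-math.log(s0[str(k)]) for k in range(1, 6)])
    if t < 1:
        return t * knots_h[0]
    return float(np.exp(np.interp(t, knots_t, np.log(knots_h))))


def framingham_initial_risk(m, sex, t, interpolate: bool = False) -> np.ndarray:
    """t-year risk ``1 - S0(t)^exp(m)`` for linear predictor(s) ``m``.

    ``sex`` may be a scalar or a per-subject array; ``t`` is a scalar
    horizon in years (integer 1..5 unless ``interpolate`` is set).
    """
    m = np.asarray(m, dtype=float)
    scalar_sex = isinstance(sex, str)
    sexes = np.full(m.shape, sex, dtype=object) if scalar_sex else np.asarray(sex, dtype=object)
    out = np.empty_like(m, dtype=float)
    for sex_key in ("male", "female"):
        mask = sexes == sex_key
        if not mask.any():
            continue
        h0 = _baseline_cumhaz(sex_key, float(t), interpolate)
        out[mask] = 1.0 - np.exp(-h0 * np.exp(m[mask]))
    return out


# ---------------------------------------------------------------------------
# Framingham-secondary (accelerated-failure-time form)
# ---------------------------------------------------------------------------

def framingham_secondary_lp(profile) -> np.ndarray:
    """Sex-specific AFT location ``m`` (higher m = longer event time)."""
    df = _as_cohort(profile)
    female = _female(df).astype(bool)
    age = _col(df, "age")
    tc = _col(df, "total_cholesterol")
    hdl = _col(df, "hdl")
    if (hdl <= 0).any() or (tc <= 0).any():
        raise InvalidInputError("hdl and total_cholesterol must be positive")
    ln_tc_hdl = np.log(tc / hdl)
    sbp = _col(df, "sbp")
    smoker = _col(df, "smoker")
    diabetes = _col(df, "diabetes") if "diabetes" in df.columns else np.ones(len(df))

    consts = load_constants()["framingham_secondary"]
    m = np.empty(len(df), dtype=float)
    for sex_key, mask in (("male", ~female), ("female", female)):
        if not mask.any():
            continue
        c = consts[sex_key]
        m[mask] = (
            c["intercept"]
            + c["age"] * age[mask]
            + c["ln_tc_hdl"] * ln_tc_hdl[mask]
            + c["ln_sbp"] * np.log(sbp[mask])
            + c["diabetes"] * diabetes[mask]
            + c["smoker"] * smoker[mask]
        )
    return m


def framingham_secondary_risk(profile, t) -> np.ndarray:
    """t-year risk ``1 - exp(-exp((ln t - m)/sigma))`` for t > 0."""
    df = _as_cohort(profile)
    t = np.asarray(t, dtype=float)
    if (t <= 0).any():
        raise InvalidInputError("horizon t must be > 0 for the secondary equations")
    m = framingham_secondary_lp(df)
    sigma = _secondary_sigma(df)
    return 1.0 - np.exp(-np.exp((np.log(t) - m) / sigma))


def _secondary_sigma(df: pd.DataFrame) -> np.ndarray:
    consts = load_constants()["framingham_secondary"]
    female = _female(df).astype(bool)
    return np.where(female, consts["female"]["sigma"], consts["male"]["sigma"])


# ---------------------------------------------------------------------------
# Cumulative hazards and the generic dispatcher
# ---------------------------------------------------------------------------

def cumulative_hazard(equation_id: str, profile, t) -> np.ndarray:
    """Model cumulative hazard H(t|x) = -ln(1 - risk(t|x)), in closed form.

    ``t`` may be a scalar or a per-subject array (each subject evaluated at
    their own time, as needed by parametric recalibration).
    """
    df = _as_cohort(profile)
    t = np.asarray(t, dtype=float)
    d = load_constants()["ukpds"]["d"]
    if equation_id == "ukpds_incident":
        return ukpds_q(df) * _ukpds_time_factor(t, d)
    if equation_id == "ukpds_duration":
        T = _col(df, "diabetes_duration")
        return ukpds_q(df) * np.power(d, T) * _ukpds_time_factor(t, d)
    if equation_id == "fram_secondary":
        if (t < 0).any():
            raise InvalidInputError("t must be >= 0")
        m = framingham_secondary_lp(df)
        sigma = _secondary_sigma(df)
        with np.errstate(divide="ignore"):
            return np.where(t > 0, np.exp((np.log(np.maximum(t, 1e-300)) - m) / sigma), 0.0)
    if equation_id == "fram_initial":
        m = framingham_initial_lp(df)
        sexes = np.asarray(df["sex"], dtype=object)
        t_b = np.broadcast_to(t, m.shape)
        h0 = np.array([_baseline_cumhaz("female" if s == "female" else "male", float(ti), True)
                       for s, ti in zip(sexes, t_b)])
        return h0 * np.exp(m)
    raise InvalidInputError(f"unknown equation_id {equation_id!r}")


def predicted_risk(equation_id: str, profile, t, interpolate: bool = False) -> np.ndarray:
    """Evaluate any of the four equations; returns per-subject probability."""
    df = _as_cohort(profile)
    if equation_id == "ukpds_incident":
        return ukpds_incident_risk(df, t)
    if equation_id == "ukpds_duration":
        return ukpds_duration_risk(df, t)
    if equation_id == "fram_initial":
        m = framingham_initial_lp(df)
        return framingham_initial_risk(m, np.asarray(df["sex"], dtype=object), t,
                                       interpolate=interpolate)
    if equation_id == "fram_secondary":
        return framingham_secondary_risk(df, t)
    raise InvalidInputError(f"unknown equation_id {equation_id!r}")


def score_cohort(cohort: pd.DataFrame, equations: Iterable[str], horizons,
                 interpolate: bool = True) -> pd.DataFrame:
    """Vectorised scoring entry point.

    Returns a long-format table (subject_id, equation_id, t, probability),
    one row per subject x equation x horizon.
    """
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    ids = cohort["subject_id"] if "subject_id" in cohort.columns else cohort.index
    frames = []
    for eq in equations:
        for t in horizons:
            frames.append(pd.DataFrame({
                "subject_id": np.asarray(ids),
                "equation_id": eq,
                "t": t,
                "probability": predicted_risk(eq, cohort, float(t), interpolate=interpolate),
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Implied hazard ratios
# ---------------------------------------------------------------------------

def _ukpds_hr_coefficients() -> Mapping[str, float]:
    c = load_constants()["ukpds"]["coefficients"]
    return {
        "age": c["age"],
        "female": c["female"],
        "afro_caribbean": c["afro_caribbean"],
        "smoker": c["smoker"],
        "hba1c": c["hba1c"],
        # the equation carries SBP per 10 mmHg; reported per 1 mmHg
        "sbp": c["sbp_per_10mmhg"] / 10.0,
        "ln_tc_hdl": c["ln_tc_hdl"],
    }


def _fram_initial_hr_coefficients(sex: str) -> Mapping[str, float]:
    c = load_constants()["framingham_initial"][sex]
    out = {"age": c["age"], "age_squared": c["age_squared"],
           "diabetes": c["diabetes"], "smoker": c["smoker"]}
    for cat in TC_CATEGORIES:
        out[f"tc_{cat}"] = c["tc"][cat]
    for cat in HDL_CATEGORIES:
        out[f"hdl_{cat}"] = c["hdl"][cat]
    for cat in BP_CATEGORIES:
        out[f"bp_{cat}"] = c["bp"][cat]
    return out


def implied_hazard_ratio(equation_id: str, covariate: str, delta: float = 1.0,
                         sex: str | None = None) -> float:
    """Hazard ratio per ``delta`` units implied by the published coefficients.

    For the proportional-hazards-form equations (UKPDS and
    Framingham-initial) the HR is ``exp(beta * delta)``.  For the
    accelerated-failure-time secondary equations a coefficient ``beta``
    inside the location ``m`` implies HR ``exp(-beta * delta / sigma)``.
    The UKPDS SBP term is carried per 10 mmHg but reported per 1 mmHg.
    """
    if equation_id in ("ukpds_incident", "ukpds_duration"):
        table = dict(_ukpds_hr_coefficients())
        if equation_id == "ukpds_duration":
            table["diabetes_duration"] = math.log(load_constants()["ukpds"]["d"])
        if covariate not in table:
            raise KeyError(f"{covariate!r} is not a covariate of {equation_id}")
        return math.exp(table[covariate] * delta)
    if equation_id in ("fram_initial", "fram_secondary"):
        if sex not in ("male", "female"):
            raise InvalidInputError(f"{equation_id} is sex-specific; pass sex=")
        if equation_id == "fram_initial":
            table = _fram_initial_hr_coefficients(sex)
            if covariate not in table:
                raise KeyError(f"{covariate!r} is not a covariate of fram_initial/{sex}")
            return math.exp(table[covariate] * delta)
        c = load_constants()["framingham_secondary"][sex]
        if covariate not in ("age", "ln_tc_hdl", "ln_sbp", "diabetes", "smoker"):
            raise KeyError(f"{covariate!r} is not a covariate of fram_secondary/{sex}")
        return math.exp(-c[covariate] * delta / c["sigma"])
    raise InvalidInputError(f"unknown equation_id {equation_id!r}")
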