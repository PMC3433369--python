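"""Synthetic managed-care diabetes cohorts for exercising the validation
pipeline.

The generator emulates a U.S. managed-care cohort of adults with
long-standing type 2 diabetes followed for a first (or recurrent) CHD
event over at most 3.5 years: covariate means/SDs and prevalences by
CHD-history stratum, administrative censoring at 3.5 years with
exponential dropout tuned to a median follow-up of about 2.7 years, two
coupled event-definition streams (a narrow MI-only definition and a
broader composite definition with a higher event rate), and
missing-completely-at-random covariate gaps ranging from about 1% (smoking)
to about 21% (HDL).

Continuous covariates are drawn from truncated normal marginals (gamma for
diabetes duration, which is skewed and non-negative) coupled through a
Gaussian copula; binary covariates are independent Bernoulli draws at the
configured prevalences.  Event times are generated by inverting the chosen
"true" cumulative-risk model at a uniform draw, so the analytic risk
function is available as an oracle for every simulated dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import risk_equations as rq
from .errors import ConfigurationError, InvalidInputError

CONTINUOUS_VARS = ("age", "hba1c", "sbp", "dbp", "total_cholesterol", "hdl",
                   "diabetes_duration")
BINARY_VARS = ("female", "afro_caribbean", "smoker")

# Lower truncation bounds keeping profiles physiologic; every bound sits
# >= 2.6 SD below the default mean, so the induced mean shift is negligible.
_LOWER_BOUNDS = {"age": 18.0, "hba1c": 3.0, "sbp": 60.0, "dbp": 30.0,
                 "total_cholesterol": 60.0, "hdl": 10.0}

# Default stratum moments and prevalences (no-CHD-history / CHD-history).
STRATUM_DEFAULTS = {
    "no_chd_history": {
        "means": {"age": 59.8, "hba1c": 8.0, "sbp": 136.4, "dbp": 78.0,
                  "total_cholesterol": 200.8, "hdl": 47.5, "diabetes_duration": 10.6},
        "sds": {"age": 12.3, "hba1c": 1.9, "sbp": 18.4, "dbp": 10.0,
                "total_cholesterol": 42.1, "hdl": 12.9, "diabetes_duration": 9.1},
        "prevalences": {"female": 0.567, "afro_caribbean": 0.173, "smoker": 0.185},
    },
    "chd_history": {
        "means": {"age": 66.1, "hba1c": 7.9, "sbp": 136.7, "dbp": 78.0,
                  "total_cholesterol": 191.9, "hdl": 44.7, "diabetes_duration": 13.6},
        "sds": {"age": 10.4, "hba1c": 1.8, "sbp": 19.8, "dbp": 10.0,
                "total_cholesterol": 45.5, "hdl": 12.8, "diabetes_duration": 10.2},
        "prevalences": {"female": 0.449, "afro_caribbean": 0.159, "smoker": 0.175},
    },
}

#: Default per-variable missing-completely-at-random rates.  Smoking and HDL
#: anchor the low and high end; the intermediate rates are plausible
#: medical-record gap rates chosen once, inside that range.
DEFAULT_MISSINGNESS = {"smoker": 0.013, "hdl": 0.207, "total_cholesterol": 0.18,
                      "hba1c": 0.06, "sbp": 0.03, "dbp": 0.03,
                      "diabetes_duration": 0.02}

#: Exponential dropout rate giving median follow-up ~2.7 y under a 3.5-y cap.
DEFAULT_DROPOUT_RATE = math.log(2.0) / 2.7

TRUE_MODELS = ("ukpds_incident", "ukpds_duration", "fram_initial",
               "fram_secondary", "ph_weibull")
OUTCOME_COLUMNS = ("subject_id", "time_ukpds", "event_ukpds",
                   "time_framingham", "event_framingham")


@dataclass
class CohortConfig:
    """Everything needed to generate one stratum of a synthetic cohort."""

    n: int = 5000
    stratum: str = "no_chd_history"
    means: Mapping[str, float] = field(default_factory=dict)       # overrides
    sds: Mapping[str, float] = field(default_factory=dict)         # overrides
    prevalences: Mapping[str, float] = field(default_factory=dict) # overrides
    correlations: Mapping[tuple, float] | None = None  # {(var_a, var_b): rho}
    true_model: str = "ukpds_incident"
    weibull_shape: float = 1.0
    weibull_scale: float = 30.0
    weibull_coefficients: Mapping[str, float] = field(default_factory=dict)
    hazard_scale: float = 1.0
    fram_event_scale: float = 1.7
    admin_horizon: float = 3.5
    dropout_rate: float = DEFAULT_DROPOUT_RATE
    missingness: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if self.stratum not in STRATUM_DEFAULTS:
            raise ConfigurationError(f"unknown stratum {self.stratum!r}")
        if self.true_model not in TRUE_MODELS:
            raise ConfigurationError(f"unknown true_model {self.true_model!r}")
        if self.admin_horizon <= 0:
            raise ConfigurationError("admin_horizon must be > 0")
        if self.dropout_rate < 0 or self.hazard_scale <= 0:
            raise ConfigurationError("dropout_rate must be >= 0 and hazard_scale > 0")
        for k, v in self.missingness.items():
            if not 0 <= v <= 1:
                raise ConfigurationError(f"missingness rate for {k} outside [0,1]")
        for k, v in {**STRATUM_DEFAULTS[self.stratum]["sds"], **self.sds}.items():
            if v < 0:
                raise ConfigurationError(f"SD for {k} must be >= 0")
        for k, v in {**STRATUM_DEFAULTS[self.stratum]["prevalences"],
                     **self.prevalences}.items():
            if not 0 <= v <= 1:
                raise ConfigurationError(f"prevalence for {k} outside [0,1]")

    def resolved_moments(self):
        base = STRATUM_DEFAULTS[self.stratum]
        means = {**base["means"], **self.means}
        sds = {**base["sds"], **self.sds}
        prev = {**base["prevalences"], **self.prevalences}
        return means, sds, prev


def _default_correlation_matrix() -> np.ndarray:
    k = len(CONTINUOUS_VARS)
    R = np.eye(k)
    idx = {v: i for i, v in enumerate(CONTINUOUS_VARS)}
    mild = ["sbp", "dbp", "total_cholesterol", "hdl"]
    for a in mild:
        for b in mild:
            if a != b:
                R[idx[a], idx[b]] = 0.1
    R[idx["sbp"], idx["dbp"]] = R[idx["dbp"], idx["sbp"]] = 0.6
    return R


def _correlation_matrix(config: CohortConfig) -> np.ndarray:
    R = _default_correlation_matrix()
    if config.correlations is not None:
        idx = {v: i for i, v in enumerate(CONTINUOUS_VARS)}
        for (a, b), rho in config.correlations.items():
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
    return R


def sample_covariates(config: CohortConfig, rng: np.random.Generator | None = None
                      ) -> pd.DataFrame:
    """Draw baseline covariates for one stratum.

    Continuous covariates: Gaussian copula with the configured correlation
    matrix, truncated-normal marginals (moment-matched gamma for diabetes
    duration).  Binary covariates: independent Bernoulli draws.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    means, sds, prev = config.resolved_moments()
    R = _correlation_matrix(config)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("correlation matrix is not positive definite") from exc

    z = rng.standard_normal((config.n, len(CONTINUOUS_VARS))) @ L.T
    u = stats.norm.cdf(z)
    # keep copula quantiles strictly inside (0, 1)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    data = {}
    for j, var in enumerate(CONTINUOUS_VARS):
        mu, sd = means[var], sds[var]
        if sd == 0:
            data[var] = np.full(config.n, mu)
        elif var == "diabetes_duration":
            shape = (mu / sd) ** 2
            scale = sd ** 2 / mu
            data[var] = stats.gamma.ppf(u[:, j], a=shape, scale=scale)
        else:
            lo = _LOWER_BOUNDS[var]
            a = (lo - mu) / sd
            data[var] = stats.truncnorm.ppf(u[:, j], a=a, b=np.inf, loc=mu, scale=sd)

    female = rng.random(config.n) < prev["female"]
    data["sex"] = np.where(female, "female", "male")
    data["afro_caribbean"] = (rng.random(config.n) < prev["afro_caribbean"]).astype(int)
    data["smoker"] = (rng.random(config.n) < prev["smoker"]).astype(int)
    data["diabetes"] = 1
    data["chd_history"] = int(config.stratum == "chd_history")
    df = pd.DataFrame(data)
    df.insert(0, "subject_id", np.arange(config.n))
    return df


def _invert_event_times(cohort: pd.DataFrame, config: CohortConfig,
                        u: np.ndarray, hazard_scale: float) -> np.ndarray:
    """Solve ``hazard_scale * H(t | x) = -ln(1 - u)`` for t, in closed form."""
    target = -np.log1p(-u) / hazard_scale
    consts = rq.load_constants()["ukpds"]
    d = consts["d"]
    if config.true_model in ("ukpds_incident", "ukpds_duration"):
        q = rq.ukpds_q(cohort)
        if config.true_model == "ukpds_duration":
            q = q * np.power(d, np.asarray(cohort["diabetes_duration"], dtype=float))
        return np.log1p((d - 1.0) * target / q) / math.log(d)
    if config.true_model == "fram_secondary":
        m = rq.framingham_secondary_lp(cohort)
        sigma = rq._secondary_sigma(cohort)
        return np.exp(m + sigma * np.log(target))
    if config.true_model == "fram_initial":
        # H(t|x) = H0(t) exp(m) with the interpolated baseline cumulative
        # hazard; baseline anchors stop at t = 5, beyond which the subject
        # outlives the administrative horizon anyway.
        m = rq.framingham_initial_lp(cohort)
        h0_target = target * np.exp(-m)
        out = np.empty(len(cohort))
        sexes = np.asarray(cohort["sex"], dtype=object)
        for sex_key in ("male", "female"):
            mask = sexes == sex_key
            if not mask.any():
                continue
            s0 = rq.load_constants()["framingham_initial"][sex_key]["baseline_survival"]
            knots_h = -np.log([s0[str(k)] for k in range(1, 6)])
            h = h0_target[mask]
            t = np.where(
                h <= knots_h[0], h / knots_h[0],
                np.interp(np.log(np.maximum(h, 1e-300)), np.log(knots_h),
                          np.arange(1.0, 6.0)))
            out[mask] = np.where(h > knots_h[-1], np.inf, t)
        return out
    # ph_weibull: H(t|x) = (t / scale)^shape * exp(lp)
    lp = np.zeros(len(cohort))
    for colname, coef in config.weibull_coefficients.items():
        lp = lp + coef * np.asarray(cohort[colname], dtype=float)
    return config.weibull_scale * np.power(target * np.exp(-lp), 1.0 / config.weibull_shape)


def simulate_followup(cohort: pd.DataFrame, config: CohortConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Attach (time, event) pairs under both CHD event definitions.

    A single latent uniform per subject drives both event streams; the
    broader (Framingham-type) definition scales the cumulative hazard by
    ``fram_event_scale`` >= 1 so its event rate exceeds the narrow
    (UKPDS-type, MI-only) rate, with coupled event times.  Censoring is the
    minimum of the administrative horizon and an exponential dropout time,
    shared by both streams.
    """
    if len(cohort) == 0:
        raise InvalidInputError("cohort is empty")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = len(cohort)
    u = np.clip(rng.random(n), 1e-15, 1 - 1e-15)
    if config.dropout_rate > 0:
        dropout = rng.exponential(1.0 / config.dropout_rate, size=n)
    else:
        dropout = np.full(n, np.inf)
    censor = np.minimum(config.admin_horizon, dropout)

    out = cohort.copy()
    for label, scale in (("ukpds", config.hazard_scale),
                         ("framingham", config.hazard_scale * config.fram_event_scale)):
        with np.errstate(over="ignore"):
            t_event = _invert_event_times(cohort, config, u, scale)
        t_event = np.where(np.isfinite(t_event), t_event, np.inf)
        event = (t_event <= censor).astype(int)
        out[f"time_{label}"] = np.minimum(t_event, censor)
        out[f"event_{label}"] = event
    return out


def inject_missingness(cohort: pd.DataFrame, rates: Mapping[str, float] | None = None,
                       rng: np.random.Generator | None = None,
                       seed: int | None = None) -> pd.DataFrame:
    """Delete covariate entries completely at random at per-variable rates.

    Outcome columns (times, event indicators, subject ids) may never be
    deleted; a rate supplied for one raises a configuration error.
    """
    rates = dict(DEFAULT_MISSINGNESS) if rates is None else dict(rates)
    for col, rate in rates.items():
        if col in OUTCOME_COLUMNS:
            raise ConfigurationError(f"refusing to delete outcome column {col!r}")
        if not 0 <= rate <= 1:
            raise ConfigurationError(f"rate for {col} outside [0,1]")
        if col not in cohort.columns:
            raise ConfigurationError(f"no such column {col!r}")
    rng = np.random.default_rng(0 if seed is None else seed) if rng is None else rng
    out = cohort.copy()
    for col, rate in rates.items():
        if rate == 0:
            continue
        mask = rng.random(len(out)) < rate
        out[col] = out[col].astype(float) if out[col].dtype.kind in "iub" else out[col]
        out.loc[mask, col] = np.nan
    return out


def generate_cohort(config: CohortConfig, with_missingness: bool = False) -> pd.DataFrame:
    """Covariates + follow-up (+ optional missingness) from one seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_fup, rng_miss = (np.random.default_rng(s) for s in ss.spawn(3))
    cohort = sample_covariates(config, rng=rng_cov)
    cohort = simulate_followup(cohort, config, rng=rng_fup)
    if with_missingness:
        cohort = inject_missingness(cohort, config.missingness, rng=rng_miss)
    return cohort


def two_stratum_cohort(n_no_chd: int, n_chd: int, seed: int = 0,
                       with_missingness: bool = False, **overrides) -> pd.DataFrame:
    """Convenience: stacked no-history + history strata, independent draws.

    The no-history stratum follows the UKPDS-engine truth; the history
    stratum follows the secondary-equation truth.  Keyword overrides are
    applied to both stratum configs.
    """
    cfg_a = CohortConfig(n=n_no_chd, stratum="no_chd_history",
                         true_model="ukpds_incident", seed=seed, **overrides)
    cfg_b = CohortConfig(n=n_chd, stratum="chd_history",
                         true_model="fram_secondary", seed=seed + 1, **overrides)
    a = generate_cohort(cfg_a, with_missingness=with_missingness)
    b = generate_cohort(cfg_b, with_missingness=with_missingness)
    b = b.assign(subject_id=b["subject_id"] + len(a))
    return pd.concat([a, b], ignore_index=True)
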