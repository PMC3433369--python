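"""End-to-end validation pipeline.

Reproduces the external-validation flow on a cohort table (simulated or
loaded): impute missing covariates, score each configured risk equation on
the appropriate CHD-history stratum, evaluate discrimination (Harrell's c,
Rubin-pooled across imputations) and decile calibration (chi-square vs the
23.2 cutoff), recalibrate and re-evaluate, then refit each equation's
predictor set as a Cox model and compare hazard ratios with the published
coefficients.

The first-event equations (UKPDS incident/duration, Framingham-initial)
are evaluated on subjects without a CHD history; the secondary equation on
subjects with one.  Framingham equations are sex-specific and evaluated
per sex.  Stratification is enforced here, not inside the estimators.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import risk_equations as rq
from .errors import ConfigurationError
from .evaluation import calibration_table, calibration_to_records, gof_chi_square, harrell_c_index
from .imputation import chained_imputation, rubin_combine
from .recalibration import recalibrate_means_and_rates, recalibrate_parametric
from .refitting import refit_equation
from .synthetic_cohort import two_stratum_cohort

log = logging.getLogger("chdval.pipeline")

#: analysis unit -> (equation, stratum, sex filter, event definition)
ANALYSIS_UNITS = {
    "ukpds_incident": ("ukpds_incident", 0, None, "ukpds"),
    "ukpds_duration": ("ukpds_duration", 0, None, "ukpds"),
    "fram_initial_male": ("fram_initial", 0, "male", "framingham"),
    "fram_initial_female": ("fram_initial", 0, "female", "framingham"),
    "fram_secondary_male": ("fram_secondary", 1, "male", "framingham"),
    "fram_secondary_female": ("fram_secondary", 1, "female", "framingham"),
}


@dataclass
class PipelineConfig:
    cohort_path: str | None = None   # load this CSV instead of simulating
    n_no_chd: int = 4000
    n_chd: int = 1600
    hazard_scale: float = 1.0
    fram_event_scale: float = 1.7
    with_missingness: bool = True
    equations: tuple = ("ukpds_incident", "ukpds_duration",
                       "fram_initial", "fram_secondary")
    t_star: float = 3.5
    G: int = 10
    bootstrap: int = 0               # 0 = analytic (Noether) c-index SE
    imputation_m: int = 5
    imputation_iterations: int = 5
    seed: int = 0
    out_dir: str = "chdval_run"

    def __post_init__(self):
        if self.t_star <= 0:
            raise ConfigurationError("t_star must be > 0")
        if self.G < 2:
            raise ConfigurationError("G must be >= 2")
        if not self.equations:
            raise ConfigurationError("no equations selected")
        unknown = set(self.equations) - set(rq.EQUATION_IDS)
        if unknown:
            raise ConfigurationError(f"unknown equations: {sorted(unknown)}")
        if self.imputation_m < 2:
            raise ConfigurationError("imputation_m must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "equations" in raw:
            raw["equations"] = tuple(raw["equations"])
        return cls(**raw)


def _units_for(config: PipelineConfig):
    return {label: spec for label, spec in ANALYSIS_UNITS.items()
            if spec[0] in config.equations}


def _evaluate_unit(label, spec, datasets, config):
    """Score, evaluate, recalibrate one analysis unit across imputations."""
    equation, stratum, sex, event_def = spec
    c_estimates, c_variances = [], []
    gof_unadj, gof_adj = [], []
    last_tables = None
    last_recal = None
    for df in datasets:
        sub = df[df["chd_history"] == stratum]
        if sex is not None:
            sub = sub[sub["sex"] == sex]
        sub = sub.reset_index(drop=True)
        times = np.asarray(sub[f"time_{event_def}"], dtype=float)
        events = np.asarray(sub[f"event_{event_def}"], dtype=int)
        pred = rq.predicted_risk(equation, sub, config.t_star, interpolate=True)
        if config.bootstrap > 0:
            c = harrell_c_index(pred, times, events, n_bootstrap=config.bootstrap,
                                seed=config.seed, ci_method="bootstrap")
            se = (c.ci_high - c.ci_low) / (2 * 1.959963984540054)
        else:
            c = harrell_c_index(pred, times, events, ci_method="noether")
            se = np.sqrt(c.c_index * (1 - c.c_index) / c.usable_pairs)
        c_estimates.append(c.c_index)
        c_variances.append(se ** 2)
        table = calibration_table(pred, times, events, config.t_star, G=config.G)
        gof_unadj.append(gof_chi_square(table).statistic)
        if equation == "fram_initial":
            recal = recalibrate_means_and_rates(sub, times, events, config.t_star,
                                                G=config.G)
        else:
            recal = recalibrate_parametric(equation, sub, times, events,
                                           t_star=config.t_star, G=config.G)
        gof_adj.append(recal.gof_after.statistic)
        last_tables = table
        last_recal = recal
        n, n_events = len(sub), int(events.sum())
    pooled_c = rubin_combine(c_estimates, c_variances)
    z = 1.959963984540054
    return {
        "label": label, "equation": equation, "n": n, "events": n_events,
        "c_index": pooled_c.estimate,
        "c_ci_low": max(0.0, pooled_c.estimate - z * pooled_c.se),
        "c_ci_high": min(1.0, pooled_c.estimate + z * pooled_c.se),
        "gof_unadjusted": float(np.mean(gof_unadj)),
        "gof_adjusted": float(np.mean(gof_adj)),
        "calibrated_unadjusted": float(np.mean(gof_unadj)) <= 23.2,
        "calibrated_adjusted": float(np.mean(gof_adj)) <= 23.2,
        "_calibration_table": last_tables,
        "_recalibration": last_recal,
    }


def _refit_unit(label, spec, datasets, config):
    """Cox refit of one unit's predictor set, Rubin-pooled across imputations."""
    equation, stratum, sex, event_def = spec
    per_imp = []
    for df in datasets:
        sub = df[df["chd_history"] == stratum]
        if sex is not None:
            sub = sub[sub["sex"] == sex]
        sub = sub.reset_index(drop=True)
        fit, comparison = refit_equation(sub, equation, event_def, G=config.G)
        per_imp.append((fit, comparison))
    names = per_imp[0][0].names
    rows = []
    for i, name in enumerate(names):
        pooled = rubin_combine([f.coef[i] for f, _ in per_imp],
                               [f.se[i] ** 2 for f, _ in per_imp])
        orig = per_imp[0][1].iloc[i]
        z = (pooled.estimate - orig["coef_orig"]) / pooled.se
        from scipy import stats as _st
        rows.append({"variable": name, "coef": pooled.estimate, "se": pooled.se,
                     "p": 2 * _st.norm.sf(abs(pooled.estimate / pooled.se)),
                     "hr": float(np.exp(pooled.estimate)),
                     "hr_orig": orig["hr_orig"], "z_vs_orig": z,
                     "p_vs_orig": 2 * _st.norm.sf(abs(z)),
                     "anticonservative": bool(orig["anticonservative"])})
    table = pd.DataFrame(rows)
    c_mean = float(np.mean([f.c_index for f, _ in per_imp]))
    gof_p_mean = float(np.mean([f.gof_p for f, _ in per_imp]))
    footer = pd.DataFrame([
        {"variable": "c_index", "coef": c_mean},
        {"variable": "gof_p", "coef": gof_p_mean},
    ])
    return pd.concat([table, footer], ignore_index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full flow and write a report bundle to ``out_dir``.

    Returns the report as a dict (summary rows, refit tables, manifest).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    if config.cohort_path:
        log.info("stage=load path=%s", config.cohort_path)
        cohort = cio.read_cohort_csv(config.cohort_path)
    else:
        log.info("stage=simulate n_no_chd=%d n_chd=%d seed=%d",
                 config.n_no_chd, config.n_chd, config.seed)
        cohort = two_stratum_cohort(
            config.n_no_chd, config.n_chd, seed=config.seed,
            with_missingness=config.with_missingness,
            hazard_scale=config.hazard_scale,
            fram_event_scale=config.fram_event_scale)
        cio.write_cohort_csv(cohort, out / "cohort.csv")
    log.info("stage=cohort n=%d events_ukpds=%d events_framingham=%d",
             len(cohort), int(cohort["event_ukpds"].sum()),
             int(cohort["event_framingham"].sum()))

    has_missing = cohort.drop(columns=["diabetes"], errors="ignore").isna().any().any()
    if has_missing:
        log.info("stage=impute m=%d iterations=%d",
                 config.imputation_m, config.imputation_iterations)
        datasets = chained_imputation(cohort, m=config.imputation_m,
                                      iterations=config.imputation_iterations,
                                      seed=config.seed)
    else:
        datasets = [cohort]

    units = _units_for(config)
    summary_rows = []
    refit_tables = {}
    for label, spec in units.items():
        log.info("stage=evaluate unit=%s", label)
        row = _evaluate_unit(label, spec, datasets, config)
        table = row.pop("_calibration_table")
        recal = row.pop("_recalibration")
        summary_rows.append(row)
        pd.DataFrame(calibration_to_records(table)).to_csv(
            out / f"calibration_{label}.tsv", sep="\t", index=False)
        with open(out / f"calibration_{label}.json", "w") as fh:
            json.dump(calibration_to_records(table), fh, indent=1)
        with open(out / f"recalibration_{label}.json", "w") as fh:
            json.dump(recal.report(), fh, indent=1)
        log.info("stage=refit unit=%s", label)
        refit_tables[label] = _refit_unit(label, spec, datasets, config)
        refit_tables[label].to_csv(out / f"refit_{label}.tsv", sep="\t",
                                   index=False, float_format="%.6g")

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.6g")
    manifest = {
        "constants_version": rq.constants_version(),
        "seed": config.seed,
        "t_star": config.t_star,
        "G": config.G,
        "imputations": len(datasets),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "run.log"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("stage=done outputs=%d", len(manifest["outputs"]))
    return {"summary": summary, "refits": refit_tables, "manifest": manifest}
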