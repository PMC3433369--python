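"""Cohort CSV schema and validated round-trip readers/writers.

One row per subject.  Columns::

    subject_id, age, sex, afro_caribbean, smoker, hba1c, sbp, dbp,
    total_cholesterol, hdl, diabetes_duration, chd_history,
    time_ukpds, event_ukpds, time_framingham, event_framingham

Missing covariate entries are encoded as empty fields and surface as NaN.
Outcome columns (times/events) must be complete.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError

REQUIRED_COLUMNS = (
    "subject_id", "age", "sex", "afro_caribbean", "smoker", "hba1c", "sbp",
    "dbp", "total_cholesterol", "hdl", "diabetes_duration", "chd_history",
    "time_ukpds", "event_ukpds", "time_framingham", "event_framingham",
)
OPTIONAL_COLUMNS = ("diabetes",)

_RANGE_CHECKS = (
    # column, lower bound, strict, reason
    ("age", 18.0, False, "equations are defined for adults (age >= 18)"),
    ("hdl", 0.0, True, "log(TC/HDL) requires hdl > 0"),
    ("total_cholesterol", 0.0, True, "log(TC/HDL) requires TC > 0"),
    ("sbp", 0.0, True, "blood pressures must be positive"),
    ("dbp", 0.0, True, "blood pressures must be positive"),
    ("diabetes_duration", 0.0, False, "diabetes duration must be >= 0"),
    ("time_ukpds", 0.0, False, "follow-up time must be >= 0"),
    ("time_framingham", 0.0, False, "follow-up time must be >= 0"),
)


def validate_cohort(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` on a malformed cohort table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table is missing required column(s): {missing}")
    for col, lo, strict, reason in _RANGE_CHECKS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = (vals < lo) | ((vals == lo) if strict else False)
        bad &= df[col].notna()
        if bad.any():
            rows = list(df.index[bad][:5])
            raise SchemaError(f"column {col!r} out of range in row(s) {rows}: {reason}")
    for col in ("afro_caribbean", "smoker", "chd_history",
                "event_ukpds", "event_framingham"):
        vals = df[col].dropna()
        if not vals.isin([0, 1]).all():
            raise SchemaError(f"column {col!r} must be 0/1")
    sex = df["sex"].dropna()
    if not sex.isin(["male", "female"]).all():
        raise SchemaError("column 'sex' must be 'male' or 'female'")
    for col in ("time_ukpds", "event_ukpds", "time_framingham", "event_framingham"):
        if df[col].isna().any():
            raise SchemaError(f"outcome column {col!r} has missing entries")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; missing entries become NaN."""
    df = pd.read_csv(path)
    validate_cohort(df)
    for col in ("event_ukpds", "event_framingham", "chd_history", "subject_id"):
        df[col] = df[col].astype(int)
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV with missing entries as empty fields."""
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, index=False, float_format="%.10g")
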