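"""CSV schemas and schema-validated readers/writers.

``trials.csv`` — one row per trial:
``subject_id, trial_index, condition{feedback|probe}, manipulation_deg
(blank for probe trials), preceding_manipulation_deg (blank for feedback
trials), instructed_amplitude_deg, epd_deg, mpd_deg, ppd_deg, max_dev_deg,
peak_speed_deg_s, status``. Angles are degrees, counterclockwise positive,
0° = subjective rightward.

``samples.csv`` — long format, one row per trajectory sample:
``subject_id, trial_index, t_s, x_deg, y_deg``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .generator import SAMPLES_COLUMNS, TRIALS_COLUMNS
from .kinematics import STATUSES

ALLOWED_AMOUNTS = {0.0, 5.0, 10.0, 20.0, 40.0}


class SchemaError(ValueError):
    """A table violates the trial/sample CSV schema."""


def _fail(path, rows, msg):
    where = ", ".join(str(r + 2) for r in rows[:5])  # +2: header + 1-based
    raise SchemaError(f"{path}: {msg} (file line(s) {where})")


def read_trials(path: str | Path, *,
                allowed_amounts=frozenset(ALLOWED_AMOUNTS)) -> pd.DataFrame:
    """Read and validate a trial table; empty-but-for-header files are fine."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "status": str})
    missing = set(TRIALS_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    df = df[TRIALS_COLUMNS].copy()
    df["status"] = df["status"].fillna("")
    if df.empty:
        return df
    bad = df.index[~df["condition"].isin(["feedback", "probe"])].tolist()
    if bad:
        _fail(path, bad, "condition must be 'feedback' or 'probe'")
    bad = df.index[~(df["status"].isin(STATUSES) | (df["status"] == ""))]
    if len(bad):
        _fail(path, bad.tolist(), f"status must be blank or one of {STATUSES}")
    for col in ("manipulation_deg", "preceding_manipulation_deg",
                "instructed_amplitude_deg", "epd_deg", "mpd_deg", "ppd_deg",
                "max_dev_deg", "peak_speed_deg_s", "trial_index"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()].tolist()
            _fail(path, bad, f"non-numeric values in {col}")
    fb = df["condition"] == "feedback"
    bad = df.index[fb & df["manipulation_deg"].isna()].tolist()
    if bad:
        _fail(path, bad, "feedback trials need manipulation_deg")
    bad = df.index[~fb & df["preceding_manipulation_deg"].isna()].tolist()
    if bad:
        _fail(path, bad, "probe trials need preceding_manipulation_deg")
    bad = df.index[fb & df["preceding_manipulation_deg"].notna()].tolist()
    if bad:
        _fail(path, bad, "feedback trials must leave "
                         "preceding_manipulation_deg blank")
    m = df["manipulation_deg"].where(fb, df["preceding_manipulation_deg"])
    bad = df.index[~m.abs().isin(allowed_amounts)].tolist()
    if bad:
        _fail(path, bad, f"|manipulation| must be one of "
                         f"{sorted(allowed_amounts)}")
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    for col in TRIALS_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df[TRIALS_COLUMNS].to_csv(path, index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(SAMPLES_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    df = df[SAMPLES_COLUMNS].copy()
    for col in ("t_s", "x_deg", "y_deg", "trial_index"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()].tolist()
            _fail(path, bad, f"non-numeric values in {col}")
    return df


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    df[SAMPLES_COLUMNS].to_csv(path, index=False)
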