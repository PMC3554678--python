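"""Per-trial and per-condition attribution / recalibration measures.

The perceived pointing direction, PPD = EPD − MPD, is the perceptual bias
of a single trial: the difference between the direction the subject reports
and the direction actually moved, counterclockwise positive.

* In a feedback trial, the offset-corrected PPD divided by the rotation
  applied to the feedback in that trial is the **relative weight of visual
  information** — the share of the visual prediction error the subject
  attributed to internal causes (1 ⇔ fully internal, 0 ⇔ fully external).
* In a perceptual probe trial, the offset-corrected PPD divided by the
  rotation applied in the *preceding* feedback trial is the **relative
  recalibration** — the single-trial aftereffect on the internal sensory
  prediction, on the same 0/1 scale.

Offset correction is per subject and per condition: feedback-trial PPDs are
referenced to the subject's mean PPD in veridical (0°) feedback trials,
probe-trial PPDs to the mean PPD of probes preceded by veridical feedback.
Quotients are computed per trial and averaged within subject afterwards;
clockwise and counterclockwise conditions of equal amount are pooled by
sign-flipping raw clockwise PPDs (quotients are already sign-normalized).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import VALID


class MissingReferenceError(ValueError):
    """A subject has no valid veridical reference trials for a condition."""


def perceived_pointing_direction(epd, mpd):
    """PPD = EPD − MPD (degrees, counterclockwise positive)."""
    return np.asarray(epd, dtype=float) - np.asarray(mpd, dtype=float)


def _condition_key(trials: pd.DataFrame, condition: str) -> pd.Series:
    if condition == "feedback":
        return trials["manipulation_deg"]
    if condition == "probe":
        return trials["preceding_manipulation_deg"]
    raise ValueError(f"unknown condition {condition!r}")


def offset_correct(trials: pd.DataFrame, condition: str) -> pd.Series:
    """Offset-corrected PPDs for all valid trials of one condition.

    Returns a Series aligned to the input index (valid trials of the
    condition only). Raises :class:`MissingReferenceError` for subjects
    without a valid veridical reference trial.
    """
    sel = trials[(trials["condition"] == condition)
                 & (trials["status"] == VALID)]
    key = _condition_key(sel, condition)
    out = pd.Series(np.nan, index=sel.index, dtype=float)
    for sid, grp in sel.groupby("subject_id", sort=False):
        ref = grp.loc[_condition_key(grp, condition) == 0.0, "ppd_deg"]
        if ref.empty:
            raise MissingReferenceError(
                f"subject {sid}: no valid veridical reference "
                f"({condition} trials)")
        out.loc[grp.index] = grp["ppd_deg"] - ref.mean()
    return out


def relative_visual_weight(ppd_corrected, manipulation):
    """Offset-corrected feedback PPD divided by that trial's rotation."""
    m = np.asarray(manipulation, dtype=float)
    if np.any(m == 0):
        raise ValueError("relative weight undefined for veridical trials")
    return np.asarray(ppd_corrected, dtype=float) / m


def relative_recalibration(ppd_corrected, preceding_manipulation):
    """Offset-corrected probe PPD divided by the preceding rotation."""
    m = np.asarray(preceding_manipulation, dtype=float)
    if np.any(m == 0):
        raise ValueError(
            "relative recalibration undefined after veridical feedback")
    return np.asarray(ppd_corrected, dtype=float) / m


def quotient_table(trials: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Per-trial quotients for one condition's valid, non-veridical trials.

    Columns: subject_id, manipulation (signed), orientation ('ccw'/'cw'),
    amount, value (the per-trial weight or recalibration quotient),
    ppd_corrected.
    """
    corrected = offset_correct(trials, condition)
    sel = trials.loc[corrected.index]
    m = _condition_key(sel, condition).to_numpy(dtype=float)
    nonzero = m != 0
    sel, corrected, m = sel[nonzero], corrected[nonzero], m[nonzero]
    value = corrected.to_numpy() / m
    return pd.DataFrame({
        "subject_id": sel["subject_id"].to_numpy(),
        "manipulation": m,
        "orientation": np.where(m > 0, "ccw", "cw"),
        "amount": np.abs(m),
        "value": value,
        "ppd_corrected": corrected.to_numpy()}, index=sel.index)


def cell_means(quotients: pd.DataFrame) -> pd.DataFrame:
    """Subject × orientation × amount mean quotients (ANOVA cells)."""
    return (quotients.groupby(["subject_id", "orientation", "amount"])
            ["value"].agg(["mean", "count"]).reset_index()
            .rename(columns={"mean": "value", "count": "n"}))


def pool_orientations(quotients: pd.DataFrame,
                      kind: str = "quotient") -> pd.DataFrame:
    """Pool clockwise and counterclockwise trials of equal amount.

    ``kind='quotient'`` concatenates values unchanged (the quotient divides
    by the signed rotation, so it is already sign-normalized);
    ``kind='ppd'`` flips the sign of clockwise-trial values first.
    """
    pooled = quotients.copy()
    if kind == "ppd":
        flip = pooled["orientation"] == "cw"
        pooled.loc[flip, "value"] = -pooled.loc[flip, "value"]
    elif kind != "quotient":
        raise ValueError(f"unknown pooling kind {kind!r}")
    return pooled


def pooled_subject_means(quotients: pd.DataFrame,
                         kind: str = "quotient") -> pd.DataFrame:
    """Subject × amount means over the orientation-pooled per-trial values."""
    pooled = pool_orientations(quotients, kind=kind)
    return (pooled.groupby(["subject_id", "amount"])["value"]
            .agg(["mean", "count"]).reset_index()
            .rename(columns={"mean": "value", "count": "n"}))


def motor_adaptation_summary(trials: pd.DataFrame) -> dict:
    """Condition means of probe-trial MPD and PPD, and their correlation.

    Conditions are the 9 signed preceding manipulations. Means are first
    taken within subject, then averaged across subjects; the Pearson
    correlation between mean MPD and mean PPD is computed across the
    condition means (df = n_conditions − 2). A negative correlation is the
    signature of motor adaptation opposing the recalibrated prediction.
    """
    sel = trials[(trials["condition"] == "probe")
                 & (trials["status"] == VALID)].copy()
    sel["m_prev"] = sel["preceding_manipulation_deg"].astype(float)
    per_subject = (sel.groupby(["subject_id", "m_prev"])
                   [["mpd_deg", "ppd_deg"]].mean().reset_index())
    cond = (per_subject.groupby("m_prev")[["mpd_deg", "ppd_deg"]]
            .mean().reset_index()
            .rename(columns={"mpd_deg": "mean_mpd", "ppd_deg": "mean_ppd"}))
    if len(cond) < 3:
        raise ValueError("need >= 3 preceding-manipulation conditions")
    r, p = stats.pearsonr(cond["mean_mpd"], cond["mean_ppd"])
    return {"condition_means": cond, "r": float(r),
            "df": len(cond) - 2, "p": float(p)}
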