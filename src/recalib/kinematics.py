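"""Trajectory kinematics: pointing direction, curvature, speed, exclusions.

The motor pointing direction (MPD) is the direction of a straight line
fitted to the outward part of the fingertip path. The fit is an orthogonal
regression constrained through the starting point (the physically anchored
origin): the MPD is the principal axis of the second-moment matrix of the
outward samples, its orientation resolved toward the movement endpoint.
This is symmetric in x and y and has no degeneracy near 90°, unlike a
coordinate regression of y on x.

Exclusion rules (all strict inequalities — a trial sitting exactly on a
threshold is retained):

* invalid_amplitude — maximum radial distance below half the instructed
  amplitude;
* invalid_no_estimate — the subject gave no direction estimate;
* excluded_curvature — maximum deviation of the outward path from the
  start→end chord above 2.25° (online-correction screen);
* excluded_velocity — instantaneous speed above 120°/s (tracker artefacts;
  computed from raw consecutive-sample finite differences, unsmoothed, so
  single-sample spikes are not hidden);
* discarded_follow — a probe trial whose immediately preceding feedback
  trial is itself non-valid (probes are read out against that trial's
  manipulation, so they are uninterpretable without it).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .generator import TrajectorySamples
from .params import AnalysisConfig

VALID = "valid"
INVALID_AMPLITUDE = "invalid_amplitude"
INVALID_NO_ESTIMATE = "invalid_no_estimate"
EXCLUDED_CURVATURE = "excluded_curvature"
EXCLUDED_VELOCITY = "excluded_velocity"
DISCARDED_FOLLOW = "discarded_follow"

STATUSES = (VALID, INVALID_AMPLITUDE, INVALID_NO_ESTIMATE,
            EXCLUDED_CURVATURE, EXCLUDED_VELOCITY, DISCARDED_FOLLOW)


def outward_segment(samples: TrajectorySamples) -> TrajectorySamples:
    """Prefix of the path up to (and including) maximum radial distance.

    Ties are broken toward the earliest maximum.
    """
    r = np.hypot(samples.x, samples.y)
    if np.max(r) <= 0:
        raise ValueError("degenerate movement: all samples at the origin")
    i = int(np.argmax(r))
    if i < 2:
        raise ValueError("degenerate movement: outward phase too short")
    return TrajectorySamples(t=samples.t[:i + 1], x=samples.x[:i + 1],
                             y=samples.y[:i + 1])


def fit_pointing_direction(samples: TrajectorySamples) -> float:
    """Direction (degrees in (-180, 180]) of the best-fit line through the
    origin, oriented toward the endpoint half-plane."""
    x, y = samples.x, samples.y
    sxx, syy, sxy = float(x @ x), float(y @ y), float(x @ y)
    if sxx + syy <= 0:
        raise ValueError("zero spatial variance: cannot fit a direction")
    # principal eigenvector of [[sxx, sxy], [sxy, syy]]
    half_trace = 0.5 * (sxx + syy)
    det = sxx * syy - sxy * sxy
    lam = half_trace + math.sqrt(max(half_trace * half_trace - det, 0.0))
    if abs(sxy) > 1e-300 * max(abs(lam - sxx), 1.0):
        vx, vy = lam - syy, sxy
    else:  # axis-aligned data
        vx, vy = (1.0, 0.0) if sxx >= syy else (0.0, 1.0)
    if vx * x[-1] + vy * y[-1] < 0:
        vx, vy = -vx, -vy
    ang = math.degrees(math.atan2(vy, vx))
    return 180.0 if ang <= -180.0 else ang


def max_chord_deviation(samples: TrajectorySamples) -> float:
    """Maximum perpendicular distance of the path from its start→end chord."""
    x0, y0 = samples.x[0], samples.y[0]
    dx, dy = samples.x[-1] - x0, samples.y[-1] - y0
    chord = math.hypot(dx, dy)
    if chord == 0:
        raise ValueError("coincident endpoints: chord undefined")
    cross = dx * (samples.y - y0) - dy * (samples.x - x0)
    return float(np.max(np.abs(cross)) / chord)


def peak_speed(samples: TrajectorySamples) -> float:
    """Maximum finite-difference speed over consecutive samples (deg/s)."""
    dt = np.diff(samples.t)
    step = np.hypot(np.diff(samples.x), np.diff(samples.y))
    return float(np.max(step / dt))


def amplitude(samples: TrajectorySamples) -> float:
    """Maximum radial distance from the starting point (degrees)."""
    return float(np.max(np.hypot(samples.x, samples.y)))


def analyze_trajectory(samples: TrajectorySamples) -> dict:
    """All kinematic measures of one movement (on its outward segment)."""
    out = outward_segment(samples)
    return {"mpd": fit_pointing_direction(out),
            "amplitude": amplitude(out),
            "max_chord_deviation": max_chord_deviation(out),
            "peak_speed": peak_speed(samples)}


def _status_for(row: pd.Series, config: AnalysisConfig) -> str:
    instructed = row["instructed_amplitude_deg"]
    if (np.isfinite(row.get("amplitude_deg", np.nan))
            and row["amplitude_deg"]
            < config.amplitude_validity_fraction * instructed):
        return INVALID_AMPLITUDE
    if not np.isfinite(row["epd_deg"]):
        return INVALID_NO_ESTIMATE
    if (np.isfinite(row["max_dev_deg"])
            and row["max_dev_deg"] > config.curvature_threshold_deg):
        return EXCLUDED_CURVATURE
    if (np.isfinite(row["peak_speed_deg_s"])
            and row["peak_speed_deg_s"] > config.speed_threshold_deg_s):
        return EXCLUDED_VELOCITY
    return VALID


def classify_and_filter(trials: pd.DataFrame,
                        samples: pd.DataFrame | None = None,
                        config: AnalysisConfig | None = None,
                        logger=None) -> pd.DataFrame:
    """Assign a validity status to every trial and refit MPD from samples.

    When ``samples`` is given, every trial must have a trajectory; MPD,
    amplitude, chord deviation and peak speed are (re)computed from it.
    Without samples the table's own kinematic columns are used where
    present and the amplitude/curvature/velocity screens are skipped for
    trials lacking them. The ``discarded_follow`` pass always runs last.
    """
    config = config or AnalysisConfig()
    trials = trials.copy().sort_values(
        ["subject_id", "trial_index"], kind="stable").reset_index(drop=True)
    trials["amplitude_deg"] = np.nan
    if samples is not None:
        groups = samples.groupby(["subject_id", "trial_index"], sort=False)
        index_of = {key: idx for key, idx in zip(
            zip(trials["subject_id"], trials["trial_index"]), trials.index)}
        seen = set()
        for key, grp in groups:
            if key not in index_of:
                raise ValueError(f"samples for unknown trial {key}")
            seen.add(key)
            traj = TrajectorySamples(t=grp["t_s"].to_numpy(),
                                     x=grp["x_deg"].to_numpy(),
                                     y=grp["y_deg"].to_numpy())
            kin = analyze_trajectory(traj)
            i = index_of[key]
            trials.loc[i, "mpd_deg"] = kin["mpd"]
            trials.loc[i, "amplitude_deg"] = kin["amplitude"]
            trials.loc[i, "max_dev_deg"] = kin["max_chord_deviation"]
            trials.loc[i, "peak_speed_deg_s"] = kin["peak_speed"]
        missing = set(index_of) - seen
        if missing:
            raise ValueError(
                f"{len(missing)} trials without trajectory samples, "
                f"e.g. {sorted(missing)[:3]}")
    trials["status"] = trials.apply(_status_for, axis=1, config=config)
    # probes following a non-valid feedback trial are unusable
    for _, idx in trials.groupby("subject_id", sort=False).groups.items():
        idx = list(idx)
        for j, i in enumerate(idx):
            if trials.loc[i, "condition"] != "probe" or j == 0:
                continue
            prev = idx[j - 1]
            if (trials.loc[prev, "condition"] == "feedback"
                    and trials.loc[prev, "status"] != VALID
                    and trials.loc[i, "status"] == VALID):
                trials.loc[i, "status"] = DISCARDED_FOLLOW
    trials["ppd_deg"] = trials["epd_deg"] - trials["mpd_deg"]
    if logger is not None:
        for _, row in trials[trials["status"] != VALID].iterrows():
            logger.debug(
                "excluded %s/%s: %s (max_dev=%.3f deg, peak_speed=%.1f deg/s, "
                "amplitude=%.2f deg)", row["subject_id"], row["trial_index"],
                row["status"], row["max_dev_deg"], row["peak_speed_deg_s"],
                row.get("amplitude_deg", float("nan")))
    return trials.drop(columns=["amplitude_deg"])
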