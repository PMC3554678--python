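"""Synthetic cohorts of alternating feedback / perceptual-probe pointing trials.

The generator embodies the generative assumptions behind the analysis:

* In a *feedback trial* the subject points in a freely chosen direction
  (MPD ~ uniform on ``mpd_range_deg``) while the online visual feedback is
  rotated by a signed angle ``m`` drawn uniformly from the manipulation set.
  The reported estimate of the movement direction mixes the efference-based
  prediction with the rotated visual feedback:
  ``EPD = MPD + offset_fb + w(|m|)·m + ε`` with the attribution weight ``w``
  decreasing in error size. The *realized* internally attributed error
  component, ``w(|m|)·m + ε``, is carried to the next trial.
* In the following *perceptual probe trial* (no feedback) the perceived
  pointing direction reveals the recalibrated internal prediction. In the
  ``attributed`` coupling mode the probe PPD is proportional to the realized
  attributed component of the preceding error with coefficient
  ``g(|m|)/w(|m|)``, gated by an error deadzone — so both the condition
  means (relative recalibration ``g``) and the within-amount trial-by-trial
  correlation emerge from a single mechanism. The ``uniform`` mode instead
  couples every probe PPD to the preceding feedback PPD with one
  coefficient ``beta_uniform`` (for slope-recovery experiments).
* The probe movement direction itself shifts opposite to the recalibrated
  prediction (``-motor_adapt_gain · g(|m|) · m``), the motor aftereffect.

Fingertip trajectories are emitted for every trial so the kinematic stage
(line fit, curvature/velocity screening) can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import GeneratorParams

TRIALS_COLUMNS = [
    "subject_id", "trial_index", "condition", "manipulation_deg",
    "preceding_manipulation_deg", "instructed_amplitude_deg", "epd_deg",
    "mpd_deg", "ppd_deg", "max_dev_deg", "peak_speed_deg_s", "status"]

SAMPLES_COLUMNS = ["subject_id", "trial_index", "t_s", "x_deg", "y_deg"]


@dataclass(frozen=True)
class TrajectorySamples:
    """Timed 2-D fingertip positions of one movement (degrees of visual angle)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t, x, y = (np.asarray(a, dtype=float) for a in (self.t, self.x, self.y))
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1 or t.size < 3:
            raise ValueError("trajectory needs >= 3 aligned samples")
        if not (np.isfinite(t).all() and np.isfinite(x).all()
                and np.isfinite(y).all()):
            raise ValueError("trajectory samples must be finite")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size


def draw_manipulation(params: GeneratorParams,
                      rng: np.random.Generator) -> float:
    """Draw one signed rotation angle, uniform over the manipulation set."""
    mset = np.asarray(params.manipulation_set, dtype=float)
    return float(mset[rng.integers(mset.size)])


def simulate_trajectory(mpd: float, params: GeneratorParams,
                        rng: np.random.Generator, *,
                        amplitude: float | None = None,
                        curvature: float | None = None) -> TrajectorySamples:
    """Simulate one centre-outward-and-back movement along direction ``mpd``.

    The radial profile is a smooth out-and-back bell ``A·sin²(π·τ)``; a
    lateral half-sine bump of signed size ``curvature`` (drawn from
    ``Normal(0, curvature_noise_sd_deg)`` when not given) bends the path so
    its maximum chord deviation from the start→peak line equals ~|curvature|.
    """
    if not math.isfinite(mpd):
        raise ValueError("mpd must be finite")
    n = params.n_traj_samples
    if amplitude is None:
        # overshoot the instructed ring slightly, never undershoot it
        amplitude = params.instructed_amplitude_deg * (
            1.0 + abs(rng.normal(0.0, 0.04)))
    if curvature is None:
        curvature = (rng.normal(0.0, params.curvature_noise_sd_deg)
                     if params.curvature_noise_sd_deg > 0 else 0.0)
    t = np.arange(n) / params.sample_rate_hz
    tau = np.linspace(0.0, 1.0, n)
    radial = amplitude * np.sin(np.pi * tau) ** 2
    lateral = curvature * np.sin(np.pi * radial / amplitude)
    ang = math.radians(mpd)
    c, s = math.cos(ang), math.sin(ang)
    x = radial * c - lateral * s
    y = radial * s + lateral * c
    return TrajectorySamples(t=t, x=x, y=y)


def simulate_feedback_trial(manipulation: float, params: GeneratorParams,
                            rng: np.random.Generator) -> dict:
    """One feedback trial; returns a record with the realized attributed
    component stored under ``attributed`` for the following probe trial."""
    amount = abs(manipulation)
    if amount != 0 and amount not in params.attribution_weight_by_amount:
        raise ValueError(f"unknown manipulation amount {amount}")
    lo, hi = params.mpd_range_deg
    mpd = rng.uniform(lo, hi)
    eps = (rng.normal(0.0, params.perceptual_noise_sd_deg)
           if params.perceptual_noise_sd_deg > 0 else 0.0)
    w = params.attribution_weight_by_amount[amount] if amount != 0 else 0.0
    attributed = w * manipulation + eps
    ppd = params.offset_fb_deg + attributed
    return {"condition": "feedback", "manipulation": manipulation,
            "mpd": mpd, "epd": mpd + ppd, "ppd_true": ppd,
            "attributed": attributed}


def simulate_probe_trial(prev: dict, params: GeneratorParams,
                         rng: np.random.Generator) -> dict:
    """One perceptual probe trial following feedback trial ``prev``."""
    if prev is None or prev.get("condition") != "feedback":
        raise ValueError("probe trial requires the preceding feedback trial")
    m_prev = prev["manipulation"]
    amount = abs(m_prev)
    eps = (rng.normal(0.0, params.perceptual_noise_sd_deg)
           if params.perceptual_noise_sd_deg > 0 else 0.0)
    above_deadzone = amount > params.deadzone_deg
    if params.coupling_mode == "attributed":
        ppd = params.offset_pp_deg + eps
        if above_deadzone:
            g = params.recal_gain_by_amount[amount]
            w = params.attribution_weight_by_amount[amount]
            if g > 0:
                ppd += (g / w) * prev["attributed"]
    else:  # uniform coupling of probe PPD to feedback PPD
        ppd = params.offset_pp_deg + params.beta_uniform * prev["ppd_true"] + eps
    g_eff = (params.recal_gain_by_amount[amount]
             if above_deadzone and amount != 0 else 0.0)
    lo, hi = params.mpd_range_deg
    mpd = rng.uniform(lo, hi) - params.motor_adapt_gain * g_eff * m_prev
    return {"condition": "probe", "preceding_manipulation": m_prev,
            "mpd": mpd, "epd": mpd + ppd, "ppd_true": ppd}


def _inject_invalidity(kind: int, params: GeneratorParams) -> dict:
    """Trajectory/estimate corruptions exercising each exclusion filter."""
    if kind == 0:    # amplitude below half the instructed ring
        return {"amplitude": 0.4 * params.instructed_amplitude_deg}
    if kind == 1:    # pronounced curvature (online correction look-alike)
        return {"curvature": 3.5}
    if kind == 2:    # ultrasound sampling artefact: single-sample jump
        return {"speed_spike": True}
    return {"drop_estimate": True}


def generate_cohort(params: GeneratorParams
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full cohort: a trial table and long-format trajectories.

    Trials strictly alternate feedback → probe (2·n_pairs per subject);
    identical params (including seed) give identical outputs.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    trial_rows: list[dict] = []
    sample_frames: list[pd.DataFrame] = []
    for subj in range(1, params.n_subjects + 1):
        sid = f"S{subj:02d}"
        for pair in range(params.n_pairs):
            m = draw_manipulation(params, rng)
            fb = simulate_feedback_trial(m, params, rng)
            pr = simulate_probe_trial(fb, params, rng)
            for k, rec in enumerate((fb, pr)):
                idx = 2 * pair + k
                corrupt: dict = {}
                if params.invalid_rate > 0 and rng.random() < params.invalid_rate:
                    corrupt = _inject_invalidity(int(rng.integers(4)), params)
                traj = simulate_trajectory(
                    rec["mpd"], params, rng,
                    amplitude=corrupt.get("amplitude"),
                    curvature=corrupt.get("curvature"))
                x, y = traj.x.copy(), traj.y.copy()
                if corrupt.get("speed_spike"):
                    j = len(traj) // 3
                    x[j] += 4.0  # 4° single-sample jump, >> 120°/s at 60 Hz
                epd = rec["epd"]
                if corrupt.get("drop_estimate"):
                    epd = np.nan
                trial_rows.append({
                    "subject_id": sid, "trial_index": idx,
                    "condition": rec["condition"],
                    "manipulation_deg": rec.get("manipulation", np.nan),
                    "preceding_manipulation_deg":
                        rec.get("preceding_manipulation", np.nan),
                    "instructed_amplitude_deg": params.instructed_amplitude_deg,
                    "epd_deg": epd, "mpd_deg": rec["mpd"],
                    "ppd_deg": np.nan, "max_dev_deg": np.nan,
                    "peak_speed_deg_s": np.nan, "status": ""})
                sample_frames.append(pd.DataFrame({
                    "subject_id": sid, "trial_index": idx,
                    "t_s": traj.t, "x_deg": x, "y_deg": y}))
    trials = pd.DataFrame(trial_rows, columns=TRIALS_COLUMNS)
    samples = pd.concat(sample_frames, ignore_index=True)[SAMPLES_COLUMNS]
    return trials, samples
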