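# Methods

## Generative model of the synthetic cohort

One subject's session is a sequence of `n_pairs` strictly alternating
feedback → probe trial pairs. All angles are degrees, counterclockwise
positive, 0° subjectively rightward; no modular wrap-around is applied
anywhere because every direction in the task lies far from a wrap seam.

**Feedback trial.** The motor pointing direction is drawn
MPD ~ U(10°, 70°), the freely-chosen-direction range observed in this kind
of task. The feedback rotation *m* is uniform over
{0°, ±5°, ±10°, ±20°, ±40°}. The reported estimate is

    EPD = MPD + offset_fb + w(|m|)·m + ε,   ε ~ N(0, σ²)

where `w(|m|)` is the attribution weight — the share of the visual error
folded into the percept — and the *realized attributed component*
`A = w(|m|)·m + ε` is carried forward to the next trial. There is no online
correction: MPD is independent of *m*.

**Probe trial.** In the default `attributed` coupling mode,

    PPD = offset_pp + [|m| > deadzone] · (g(|m|)/w(|m|)) · A + ε′

so the *expected* probe PPD after rotation *m* is `g(|m|)·m` (the condition
means recover the recalibration gains), while trial-to-trial fluctuations
of the attributed component propagate into the probe — producing the
positive within-amount correlation between feedback-trial and probe-trial
PPD from the same single mechanism. A mean-only model could not produce
that correlation, which is why the coupling acts on the realized component
rather than on `m` directly. The alternative `uniform` mode sets
`PPD = offset_pp + β·PPD_fb_prev + ε′` for every pair regardless of amount;
it exists for slope-recovery experiments where the ground-truth regression
coefficient must be a single known β. The probe movement direction is
`U(10°, 70°) − motor_adapt_gain·g(|m|)·m`: motor behaviour compensates for
the recalibrated prediction, giving the negative condition-level
correlation between mean motor and mean perceived direction.

**Trajectories.** Each movement is an out-and-back path: radial profile
`A·sin²(πτ)` (peak amplitude slightly above the 9.0° instructed ring, so
feedback is always visible beyond 4.5°), plus a lateral half-sine bump
whose signed size is drawn from N(0, `curvature_noise_sd_deg`). The bump
makes the maximum chord deviation of the outward path ≈ |bump| and
perturbs the fitted direction slightly and symmetrically, so the kinematic
stage operates on non-trivial input. With `invalid_rate > 0` a random
subset of trials is corrupted (short amplitude, strong curvature, a
single-sample velocity spike, or a missing estimate) to exercise every
exclusion filter; by default no invalid trials are produced.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| `n_subjects`, `n_pairs` | 11, 180 | the study's cohort dimensions |
| `attribution_weight_by_amount` | 0.54, 0.57, 0.38, 0.19 at 5/10/20/40° | the reported weight profile |
| `recal_gain_by_amount` | 0, 0.20, 0.14, 0.07 | the reported recalibration profile; 0 at 5° = deadzone |
| `deadzone_deg` | 5 | recalibration absent at 5° |
| `beta_uniform` | 0.219 | the reported mean trial-by-trial regression coefficient |
| `perceptual_noise_sd_deg` | 4 | **assumption** — not reported; chosen so single-trial weight estimates scatter with SDs of roughly 0.2–0.8 across amounts, matching the reported trial-level histograms' visual spread |
| `motor_adapt_gain` | 1 | **assumption** — full compensation of the recalibrated prediction; only the sign of the resulting correlation is constrained by the data |
| `offset_fb_deg`, `offset_pp_deg` | 0 | offsets exist in real data; defaults 0, configurable so offset correction is exercised |
| `mpd_range_deg` | (10, 70) | observed spread of freely chosen directions |
| `curvature_noise_sd_deg` | 0.3 | keeps essentially all clean trials below the 2.25° exclusion bound while making the line fit non-trivial |
| `n_traj_samples`, `sample_rate_hz` | 60, 60 | 1-s movements at the tracker's 60 Hz |

The noise and motor-gain assumptions were fixed once, before any recovery
experiment, and are not tuned.

## Analysis conventions

* **Line fit.** Orthogonal regression through the starting point: the MPD
  is the principal axis of the outward samples' second-moment matrix,
  oriented toward the endpoint. This is symmetric in x/y and has no
  degeneracy near 90°, unlike regressing y on x.
* **Outward segment.** Prefix of the path through the (first) maximum of
  radial distance.
* **Exclusions.** Strict inequalities (`>` 2.25° chord deviation,
  `>` 120°/s, amplitude `<` half the instructed 9.0°); a trial exactly on
  a threshold is retained. Speed uses raw consecutive-sample finite
  differences without smoothing, because the velocity rule targets
  single-sample tracker artefacts that smoothing would hide. The
  `discarded_follow` pass (probes after non-valid feedback) runs last.
* **Offset correction** is computed per subject and condition from *valid*
  trials only, after kinematic filtering. Feedback reference: veridical
  (0°) feedback trials; probe reference: probes preceded by veridical
  feedback. After correction the reference trials average exactly zero.
* **Quotients** are computed per trial and averaged within subject
  (the trial-level weight distribution is itself an object of analysis),
  veridical trials never enter a quotient, and pooling across orientations
  concatenates per-trial quotients unchanged (they are sign-normalized by
  construction) while raw PPDs from clockwise cells are sign-flipped.
* **ANOVA.** Balanced two-way within-subject decomposition on subject ×
  orientation × amount cell means. Mauchly's test (chi-square with Box's
  second-order correction, the ezANOVA convention) and the
  Greenhouse–Geisser epsilon are computed per multi-level effect from the
  orthonormal-contrast covariance; the reported p uses GG-corrected dfs
  whenever Mauchly rejects at α = .05, and epsilon is always reported. For
  two-level effects sphericity holds trivially (ε = 1, F = t²). The
  implementation is cross-checked against pingouin in the test suite.
* **Planned tests** are one-tailed with directions fixed a priori (weights
  and recalibration decrease with amount; quotients and correlations are
  positive). Bonferroni families: 3 for the sequential adjacent-amount
  contrasts, 4 for the one-sample tests across amounts — correction within
  each measure. Effect size r = √(t²/(t²+df)).
* **Trial-by-trial regression.** OLS of probe PPD on the immediately
  preceding feedback PPD over valid consecutive pairs, per subject
  (overall, and restricted per absolute amount). Per-subject r values are
  averaged raw (no Fisher z), matching the mean ± SE convention; subject
  significance is judged at α = .05 uncorrected, two-sided. Pairs following
  veridical feedback are included in the overall regression (a config flag
  excludes them).
* **Bayes factors.** B = ∫₀^∞ N(mean; θ, se)·2N(θ; 0, 0.5) dθ / N(mean; 0, se):
  half-normal H1 prior with mode 0 and SD 0.5 on the per-amount mean
  within-subject correlation, point-null denominator. Adaptive quadrature
  with relative tolerance ≤ 1e-6 (in practice ~1e-10); the ratio is formed
  in log space so that overwhelming evidence reports `inf` rather than
  overflowing. B > 3 / B < 1/3 mark substantial evidence.
* **Unimodality screen.** Shapiro–Wilk per subject × amount on the
  per-trial weights, p ≥ .05 uncorrected counted as tenable; constant or
  n < 3 cells are flagged and excluded from the count.
* **Masson–Loftus normalization** removes `M_i − GM` from every score;
  condition means are preserved exactly and the normalized SEs reflect
  within-subject variability only. Reports carry both raw and normalized
  SEs, labelled.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on:
alternation, the discrete uniform manipulation distribution, error-size-
dependent attribution, deadzone-gated single-trial recalibration coupled to
the realized attributed component, motor adaptation opposing recalibration,
constant per-condition offsets, and (optionally) kinematically invalid
trials. It does not model biomechanics, reaction/movement times, online
corrections, eye movements, learning drift across the session, or
heteroscedastic perceptual noise. Passing parameter-recovery tests
therefore shows that the *pipeline* is unbiased and correctly assembled
under the stated generative assumptions — not that those assumptions
exhaust real behaviour.

## Problem sizes and numerical choices

The acceptance script averages each recovery estimate over 8 replicate
cohorts at the study conditions (11 × 180 pairs; independent child seeds
derived from `--seed` via `numpy.random.SeedSequence`), reducing the
Monte-Carlo SE of the single-cohort estimator (which a direct simulation
shows to be unbiased, per-cohort SD ≈ 0.01 for the recalibration at 20°)
by √8. Unit tests use 2–5-subject cohorts with 40–120 pairs — large enough
that every amount × orientation cell is populated with overwhelming
probability. Degenerate inputs are rejected with explicit errors
(no-estimate trials, missing offset references, zero-variance regressions,
incomplete ANOVA tables, singular Mauchly covariances reported as
untestable rather than significant). Angles are kept as plain reals
throughout; the only tie-break (equal radial maxima) takes the earliest
sample.

## Known limitations

* The perceptual noise SD and the motor-adaptation gain are assumptions;
  only qualitative features (scatter magnitude, correlation sign) constrain
  them.
* The generator's probe coupling is exactly linear in the attributed
  component; saturation or retention dynamics across trials are not
  modelled, so multi-trial learning curves are out of scope.
* With trial tables supplied without raw trajectories, the curvature and
  velocity screens can only use pre-computed columns if present; absent
  those columns, such trials pass the kinematic screens by construction.
* The two-way ANOVA requires a complete balanced subject × cell table and
  deliberately refuses imputation.
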