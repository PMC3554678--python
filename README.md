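# recalib

Trial-by-trial analysis of how the brain decides *whose fault an error is* —
and recalibrates its sensory predictions accordingly — in visuomotor
pointing, together with a synthetic cohort generator that makes every stage
of the analysis testable against known ground truth.

## The scientific problem

When a reaching movement produces visual feedback that deviates from what
the motor system predicted (a *visual prediction error*), the nervous system
must attribute that error to internal causes (its own sensorimotor system)
or to external ones (the world) before deciding whether to adapt. The
paradigm analysed here alternates two trial types:

* **Feedback trials** — the subject points in a freely chosen direction
  (MPD, motor pointing direction) while the cursor is rotated by a signed
  angle *m* drawn from {0°, ±5°, ±10°, ±20°, ±40°}; they then report the
  direction they believe they moved (EPD, estimated pointing direction).
* **Perceptual probe trials** — the same movement without any feedback,
  probing the current state of the internal sensory prediction.

The per-trial perceptual bias is **PPD = EPD − MPD**. Two quotients carry
the analysis:

* relative weight of visual information
  `w = PPD_feedback (offset-corrected) / m` — the internally attributed
  share of the prediction error (1 ⇔ fully internal, 0 ⇔ fully external);
* relative recalibration
  `g = PPD_probe (offset-corrected) / m_prev` — the single-trial aftereffect
  of the preceding error on the internal prediction.

The package implements the complete pipeline around those quantities:
trajectory kinematics (orthogonal line fit through the start point,
curvature/velocity/amplitude exclusions, discarding probes after invalid
feedback), per-subject offset correction, orientation pooling, two-way
repeated-measures ANOVA with Mauchly's test and Greenhouse–Geisser
correction, planned one-tailed contrasts with Bonferroni correction and
effect sizes, per-subject trial-by-trial regressions, half-normal-prior
Bayes factors, Shapiro–Wilk unimodality screening, Masson–Loftus
within-subject error bars, and a motor-adaptation summary.

Because no raw cohort data are publicly available, the package ships a
first-class generator (`recalib.generator`) whose defaults encode the study
conditions (11 subjects × 180 feedback/probe pairs; attribution weights
0.54/0.57/0.38/0.19 and recalibration gains 0/0.20/0.14/0.07 at
5/10/20/40°; 5° error deadzone), so the full analysis can be validated by
parameter recovery.

## Worked example

```python
from recalib import GeneratorParams, generate_cohort, AttributionModel

trials, samples = generate_cohort(GeneratorParams(seed=42))
results = AttributionModel(trials, samples).fit()
print(results.pooled_weights.round(4))
```

```
 amount   mean     se  n_subjects  se_normalized
    5.0 0.5757 0.0374          11         0.0296
   10.0 0.5691 0.0199          11         0.0190
   20.0 0.3850 0.0094          11         0.0099
   40.0 0.1942 0.0050          11         0.0103
```

The pooled relative visual weight decreases with error size — small errors
are attributed mostly internally, large ones externally — and recovers the
generator's 0.54/0.57/0.38/0.19 profile within Monte-Carlo error.
`results.pooled_recalibration` shows the matching recalibration profile
with no recalibration at 5° (the error deadzone), `results.summary()`
prints the full statistical report (ANOVAs, contrasts, regressions, Bayes
factors, unimodality counts, motor-adaptation correlation), and
`results.plot_profiles("profiles.png")` draws both profiles. On this cohort
the condition-level correlation between probe-trial motor and perceived
pointing direction is r(7) = −0.89: the motor system adapts *against* the
recalibrated prediction.

The same analysis runs from the shell:

```bash
recalib simulate --seed 42 --out cohort/
recalib analyze --trials cohort/trials.csv --samples cohort/samples.csv --out report/
recalib reproduce --out report/   # simulate + analyze in one step
```

CSV schemas, YAML/JSON configuration and the `params.json` sidecar are
documented in `recalib/io.py` and `recalib/params.py`.

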