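"""Model/Results interface tying the full analysis together.

:class:`AttributionModel` wraps a cohort trial table (plus, optionally, raw
fingertip trajectories) and, on :meth:`~AttributionModel.fit`, runs the
complete chain — kinematic filtering, offset correction, per-trial
attribution and recalibration quotients, orientation pooling, the two-way
repeated-measures ANOVAs, planned contrasts, trial-by-trial regressions,
half-normal Bayes factors, the unimodality screen and the motor-adaptation
summary — returning an :class:`AttributionResults` object that carries every
estimate with its uncertainty and renders a text summary.

Example
-------
>>> from recalib import GeneratorParams, generate_cohort, AttributionModel
>>> trials, samples = generate_cohort(GeneratorParams(seed=42))
>>> res = AttributionModel(trials, samples).fit()
>>> res.pooled_weights  # per-amount mean +/- SE of the visual weight
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics, measures, stats as rstats
from .kinematics import VALID
from .params import AnalysisConfig


def _pooled_summary(subject_means: pd.DataFrame) -> pd.DataFrame:
    """Across-subject mean, raw SE and Masson–Loftus-normalized SE per amount."""
    wide = subject_means.pivot(index="subject_id", columns="amount",
                               values="value")
    out = pd.DataFrame({
        "amount": wide.columns.to_numpy(dtype=float),
        "mean": wide.mean().to_numpy(),
        "se": (wide.std(ddof=1) / math.sqrt(len(wide))).to_numpy(),
        "n_subjects": wide.notna().sum().to_numpy()})
    if not wide.isna().any().any():
        norm = rstats.masson_loftus_normalize(wide)
        out["se_normalized"] = (norm.std(ddof=1)
                                / math.sqrt(len(norm))).to_numpy()
    else:
        out["se_normalized"] = np.nan
    return out.reset_index(drop=True)


@dataclass
class AttributionResults:
    """Estimates, uncertainties and diagnostics of one fitted cohort."""

    trials: pd.DataFrame
    config: AnalysisConfig
    pooled_weights: pd.DataFrame
    pooled_recalibration: pd.DataFrame
    weight_cells: pd.DataFrame
    recal_cells: pd.DataFrame
    weight_subject_means: pd.DataFrame
    recal_subject_means: pd.DataFrame
    weight_anova: rstats.AnovaResult
    recal_anova: rstats.AnovaResult
    weight_contrasts: list
    recal_contrasts: list
    weight_vs_zero: list
    recal_vs_zero: list
    regression_by_subject: pd.DataFrame
    regression_aggregate: dict
    bayes_factors: pd.DataFrame
    unimodality: pd.DataFrame
    motor: dict
    trial_accounting: pd.DataFrame
    amounts: list = field(default_factory=list)

    # -- convenience accessors ------------------------------------------
    def weight_at(self, amount: float) -> float:
        t = self.pooled_weights
        return float(t.loc[t["amount"] == amount, "mean"].iloc[0])

    def recalibration_at(self, amount: float) -> float:
        t = self.pooled_recalibration
        return float(t.loc[t["amount"] == amount, "mean"].iloc[0])

    def mean_regression_slope(self) -> float:
        return float(self.regression_by_subject["slope"].mean())

    def mean_regression_r(self) -> float:
        return float(self.regression_by_subject["r"].mean())

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        buf = io.StringIO()
        w = buf.write
        w("Causal attribution of visual prediction errors — cohort fit\n")
        w("=" * 63 + "\n\n")
        acct = self.trial_accounting
        w("Trial accounting (per status):\n")
        w(acct.to_string(index=False) + "\n\n")
        w("Relative weight of visual information (pooled ±amounts):\n")
        w(self.pooled_weights.round(4).to_string(index=False) + "\n\n")
        w("Relative recalibration of internal sensory predictions:\n")
        w(self.pooled_recalibration.round(4).to_string(index=False) + "\n\n")
        w("Repeated-measures ANOVA — relative weight:\n")
        w(self.weight_anova.to_frame().round(4).to_string(index=False)
          + "\n\n")
        w("Repeated-measures ANOVA — relative recalibration:\n")
        w(self.recal_anova.to_frame().round(4).to_string(index=False)
          + "\n\n")
        w("Planned contrasts (one-tailed, Bonferroni within measure):\n")
        for name, tests in (("weight", self.weight_contrasts),
                            ("recalibration", self.recal_contrasts)):
            for t in tests:
                w(f"  {name} {t.label}: t({t.df}) = {t.t:.3f}, "
                  f"p = {t.p_bonferroni:.4f}, r = {t.effect_r:.2f}\n")
        w("\nOne-sample tests vs 0 (one-tailed, Bonferroni):\n")
        for name, tests in (("weight", self.weight_vs_zero),
                            ("recalibration", self.recal_vs_zero)):
            for t in tests:
                w(f"  {name} {t.label}: t({t.df}) = {t.t:.3f}, "
                  f"p = {t.p_bonferroni:.4f}\n")
        agg = self.regression_aggregate
        w("\nTrial-by-trial regression (probe PPD on preceding feedback "
          "PPD):\n")
        w(f"  mean r = {agg['r_mean']:.3f} ± {agg['r_se']:.3f}, "
          f"mean slope = {agg['slope_mean']:.3f} ± {agg['slope_se']:.3f}, "
          f"significant subjects: {agg['n_significant']}/"
          f"{agg['n_subjects']}\n\n")
        w("Bayes factors (half-normal prior, per-amount mean r):\n")
        w(self.bayes_factors.round(3).to_string(index=False) + "\n\n")
        uni = self.unimodality
        w(f"Unimodality screen: {int(uni['tenable'].sum())}/"
          f"{len(uni)} subject × amount samples tenable "
          f"(Shapiro–Wilk p ≥ {self.config.alpha:g})\n\n")
        w("Motor adaptation (probe trials):\n")
        w(f"  condition-level r({self.motor['df']}) = "
          f"{self.motor['r']:.3f}, p = {self.motor['p']:.4f}\n")
        return buf.getvalue()

    def to_json_dict(self) -> dict:
        """JSON-serialisable summary of all headline numbers."""
        def tests_dict(tests):
            return [{"label": t.label, "t": t.t, "df": t.df,
                     "p_raw": t.p_raw, "p_bonferroni": t.p_bonferroni,
                     "effect_r": t.effect_r, "mean": t.mean, "se": t.se}
                    for t in tests]

        agg = self.regression_aggregate
        return {
            "pooled_weights": self.pooled_weights.to_dict("records"),
            "pooled_recalibration":
                self.pooled_recalibration.to_dict("records"),
            "weight_anova": self.weight_anova.to_frame().to_dict("records"),
            "recal_anova": self.recal_anova.to_frame().to_dict("records"),
            "weight_contrasts": tests_dict(self.weight_contrasts),
            "recal_contrasts": tests_dict(self.recal_contrasts),
            "weight_vs_zero": tests_dict(self.weight_vs_zero),
            "recal_vs_zero": tests_dict(self.recal_vs_zero),
            "regression": {k: v for k, v in agg.items()},
            "bayes_factors": self.bayes_factors.to_dict("records"),
            "unimodality_tenable": int(self.unimodality["tenable"].sum()),
            "unimodality_total": int(len(self.unimodality)),
            "motor": {"r": self.motor["r"], "df": self.motor["df"],
                      "p": self.motor["p"]},
            "trial_accounting": self.trial_accounting.to_dict("records"),
        }

    def save(self, outdir: str | Path) -> None:
        """Write report CSV tables and the JSON summary to ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pooled_weights.to_csv(outdir / "pooled_weights.csv", index=False)
        self.pooled_recalibration.to_csv(
            outdir / "pooled_recalibration.csv", index=False)
        self.weight_anova.to_frame().to_csv(
            outdir / "anova_weight.csv", index=False)
        self.recal_anova.to_frame().to_csv(
            outdir / "anova_recalibration.csv", index=False)
        self.regression_by_subject.to_csv(
            outdir / "regression_by_subject.csv", index=False)
        self.bayes_factors.to_csv(outdir / "bayes_factors.csv", index=False)
        self.unimodality.to_csv(outdir / "unimodality.csv", index=False)
        self.motor["condition_means"].to_csv(
            outdir / "motor_condition_means.csv", index=False)
        self.trial_accounting.to_csv(
            outdir / "trial_accounting.csv", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(self.to_json_dict(), indent=2, sort_keys=True,
                       default=float) + "\n")
        (outdir / "summary.txt").write_text(self.summary())

    def plot_profiles(self, path: str | Path | None = None):
        """Weight and recalibration profiles vs amount (mean ± normalized SE)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(8, 3.2), sharex=True)
        for ax, table, title in (
                (axes[0], self.pooled_weights, "relative visual weight"),
                (axes[1], self.pooled_recalibration,
                 "relative recalibration")):
            ax.errorbar(table["amount"], table["mean"],
                        yerr=table["se_normalized"].fillna(table["se"]),
                        marker="o")
            ax.axhline(0.0, color="0.6", lw=0.8)
            ax.set_xlabel("amount of manipulation (deg)")
            ax.set_title(title)
            ax.set_xscale("log")
            ax.set_xticks(table["amount"])
            ax.get_xaxis().set_major_formatter(
                matplotlib.ticker.ScalarFormatter())
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


class AttributionModel:
    """Full trial-by-trial attribution/recalibration analysis of one cohort.

    Parameters
    ----------
    trials : DataFrame in the trial-table schema (see :mod:`recalib.io`).
    samples : optional long-format trajectory table; when given, motor
        pointing directions and the kinematic exclusion measures are
        recomputed from the raw paths before filtering.
    config : :class:`AnalysisConfig` with thresholds and conventions.
    """

    def __init__(self, trials: pd.DataFrame,
                 samples: pd.DataFrame | None = None,
                 config: AnalysisConfig | None = None,
                 logger=None) -> None:
        self.trials = trials
        self.samples = samples
        self.config = config or AnalysisConfig()
        self.logger = logger

    @classmethod
    def from_csv(cls, trials_path: str | Path,
                 samples_path: str | Path | None = None,
                 config: AnalysisConfig | None = None) -> "AttributionModel":
        from .io import read_samples, read_trials
        trials = read_trials(trials_path)
        samples = read_samples(samples_path) if samples_path else None
        return cls(trials, samples, config)

    # -- pieces ---------------------------------------------------------
    def _regressions(self, trials: pd.DataFrame) -> tuple[pd.DataFrame, dict,
                                                          pd.DataFrame]:
        """Per-subject OLS of probe PPD on preceding feedback PPD, overall
        and per absolute preceding manipulation; Bayes factors per amount."""
        cfg = self.config
        pairs = []
        by_subject = {sid: g.sort_values("trial_index")
                      for sid, g in trials.groupby("subject_id", sort=False)}
        for sid, g in by_subject.items():
            rows = g.reset_index(drop=True)
            for i in range(1, len(rows)):
                fb, pr = rows.iloc[i - 1], rows.iloc[i]
                if (fb["condition"] == "feedback" and pr["condition"] == "probe"
                        and fb["status"] == VALID and pr["status"] == VALID):
                    pairs.append({
                        "subject_id": sid,
                        "amount": abs(float(fb["manipulation_deg"])),
                        "fb_ppd": float(fb["ppd_deg"]),
                        "probe_ppd": float(pr["ppd_deg"])})
        pairs = pd.DataFrame(pairs)
        reg_rows = []
        for sid, g in pairs.groupby("subject_id"):
            use = g if cfg.include_veridical_in_overall_regression \
                else g[g["amount"] > 0]
            try:
                res = rstats.trial_regression(use["fb_ppd"], use["probe_ppd"])
            except ValueError:
                continue
            reg_rows.append({"subject_id": sid, "r": res.r,
                             "slope": res.slope, "intercept": res.intercept,
                             "df": res.df, "p": res.p, "n": res.n,
                             "significant": res.p < cfg.alpha})
        reg = pd.DataFrame(reg_rows)
        agg_t = rstats.aggregate_within_subject_r(reg["r"])
        aggregate = {
            "r_mean": agg_t.mean, "r_se": agg_t.se, "r_t": agg_t.t,
            "r_df": agg_t.df, "r_p_one_tailed": agg_t.p_raw,
            "slope_mean": float(reg["slope"].mean()),
            "slope_se": float(reg["slope"].std(ddof=1)
                              / math.sqrt(len(reg))),
            "n_significant": int(reg["significant"].sum()),
            "n_subjects": int(len(reg))}
        bf_rows = []
        for amount, g in pairs.groupby("amount"):
            rs = []
            for sid, gg in g.groupby("subject_id"):
                try:
                    rs.append(rstats.trial_regression(
                        gg["fb_ppd"], gg["probe_ppd"]).r)
                except ValueError:
                    continue
            rs = np.asarray(rs)
            if rs.size < 3:
                continue
            mean = float(rs.mean())
            se = float(rs.std(ddof=1) / math.sqrt(rs.size))
            if se > 0:
                B = rstats.dienes_bayes_factor(mean, se, cfg.bf_prior_sd).B
            else:  # degenerate noiseless cohort: evidence is unbounded
                B = math.inf if mean > 0 else 0.0
            bf_rows.append({"amount": amount, "r_mean": mean, "r_se": se,
                            "B": B, "n_subjects": rs.size})
        return reg, aggregate, pd.DataFrame(bf_rows)

    # -- fit ------------------------------------------------------------
    def fit(self) -> AttributionResults:
        cfg = self.config
        trials = kinematics.classify_and_filter(
            self.trials, self.samples, cfg, logger=self.logger)
        acct = (trials.groupby(["condition", "status"]).size()
                .reset_index(name="n_trials"))

        weight_q = measures.quotient_table(trials, "feedback")
        recal_q = measures.quotient_table(trials, "probe")
        amounts = sorted(weight_q["amount"].unique())

        weight_cells = measures.cell_means(weight_q)
        recal_cells = measures.cell_means(recal_q)
        weight_sm = measures.pooled_subject_means(weight_q)
        recal_sm = measures.pooled_subject_means(recal_q)
        pooled_w = _pooled_summary(weight_sm)
        pooled_g = _pooled_summary(recal_sm)

        weight_anova = rstats.rm_anova_2way(weight_cells)
        recal_anova = rstats.rm_anova_2way(recal_cells)
        weight_contrasts = rstats.planned_contrasts(weight_sm, amounts)
        recal_contrasts = rstats.planned_contrasts(recal_sm, amounts)
        weight_vs_zero = rstats.one_sample_tests(weight_sm, amounts)
        recal_vs_zero = rstats.one_sample_tests(recal_sm, amounts)

        reg, reg_agg, bfs = self._regressions(trials)
        unimodality = rstats.unimodality_screen(weight_q, alpha=cfg.alpha)
        motor = measures.motor_adaptation_summary(trials)

        return AttributionResults(
            trials=trials, config=cfg, pooled_weights=pooled_w,
            pooled_recalibration=pooled_g, weight_cells=weight_cells,
            recal_cells=recal_cells, weight_subject_means=weight_sm,
            recal_subject_means=recal_sm, weight_anova=weight_anova,
            recal_anova=recal_anova, weight_contrasts=weight_contrasts,
            recal_contrasts=recal_contrasts, weight_vs_zero=weight_vs_zero,
            recal_vs_zero=recal_vs_zero, regression_by_subject=reg,
            regression_aggregate=reg_agg, bayes_factors=bfs,
            unimodality=unimodality, motor=motor, trial_accounting=acct,
            amounts=amounts)
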