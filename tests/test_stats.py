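"""Inference: rm-ANOVA/sphericity, contrasts, regression, Bayes factors,
unimodality screening and Masson–Loftus normalization, each against an
independent oracle."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as st

from recalib.stats import (aggregate_within_subject_r, dienes_bayes_factor,
                           gg_epsilon, masson_loftus_normalize, mauchly,
                           one_sample_tests, planned_contrasts, rm_anova_2way,
                           trial_regression, unimodality_screen)


def _cells(rng, n_subjects=6, noise_by_amount=None):
    noise_by_amount = noise_by_amount or {5: 1.0, 10: 0.5, 20: 0.3, 40: 0.8}
    truth = {5: 0.5, 10: 0.55, 20: 0.4, 40: 0.2}
    rows = []
    for s in range(n_subjects):
        base = rng.normal(0, 0.3)
        for o in ("ccw", "cw"):
            for a in (5.0, 10.0, 20.0, 40.0):
                rows.append({"subject_id": f"S{s:02d}", "orientation": o,
                             "amount": a,
                             "value": truth[a] + base
                             + rng.normal(0, noise_by_amount[a])})
    return pd.DataFrame(rows)


# -- repeated-measures ANOVA ----------------------------------------------

def test_rm_anova_zero_variance_gives_zero_f():
    rows = [{"subject_id": f"S{s}", "orientation": o, "amount": a,
             "value": 0.7}
            for s in range(4) for o in ("ccw", "cw")
            for a in (5.0, 10.0, 20.0, 40.0)]
    res = rm_anova_2way(pd.DataFrame(rows))
    for effect in res.effects.values():
        assert effect.F == 0.0


def test_rm_anova_matches_pingouin_two_way(rng):
    cells = _cells(rng)
    mine = rm_anova_2way(cells)
    ref = pg.rm_anova(data=cells, dv="value",
                      within=["orientation", "amount"],
                      subject="subject_id", detailed=True)
    ref = ref.set_index("Source")
    for name, key in [("orientation", "orientation"), ("amount", "amount"),
                      ("orientation*amount", "orientation * amount")]:
        e = mine[name]
        assert e.F == pytest.approx(ref.loc[key, "F"], rel=1e-10)
        assert e.df_num == ref.loc[key, "ddof1"]
        assert e.df_den == ref.loc[key, "ddof2"]
        assert e.p == pytest.approx(ref.loc[key, "p_unc"], rel=1e-10)
        assert e.epsilon_gg == pytest.approx(ref.loc[key, "eps"], rel=1e-9)
        assert e.p_gg == pytest.approx(ref.loc[key, "p_GG_corr"], rel=1e-8)
        assert e.df_num_gg == pytest.approx(e.df_num * e.epsilon_gg)
        assert 0.0 <= e.p <= 1.0


def test_rm_anova_two_level_factor_equals_paired_t(rng):
    cells = _cells(rng)
    res = rm_anova_2way(cells)
    wide = (cells.groupby(["subject_id", "orientation"])["value"].mean()
            .unstack())
    t = st.ttest_rel(wide["ccw"], wide["cw"]).statistic
    assert res["orientation"].F == pytest.approx(t * t, abs=1e-8)
    assert res["orientation"].epsilon_gg == 1.0
    assert res["orientation"].mauchly_p == 1.0


def test_rm_anova_rejects_incomplete_table(rng):
    cells = _cells(rng).iloc[1:]
    with pytest.raises(ValueError, match="incomplete|crossing"):
        rm_anova_2way(cells)


# -- epsilon and Mauchly ---------------------------------------------------

def test_gg_epsilon_compound_symmetry_is_one():
    S = 0.3 * np.eye(4) + 0.5
    assert gg_epsilon(S) == pytest.approx(1.0)


def test_gg_epsilon_attains_lower_bound():
    v = np.array([1.0, -1.0, 0.0, 0.0])
    assert gg_epsilon(np.outer(v, v)) == pytest.approx(1.0 / 3.0)


def test_gg_epsilon_matches_eigenvalue_oracle(rng):
    A = rng.normal(size=(4, 4))
    S = A @ A.T + 0.5 * np.eye(4)
    k = S.shape[0]
    C = np.eye(k) - np.ones((k, k)) / k
    lam = np.linalg.eigvalsh(C @ S @ C)
    lam = lam[lam > 1e-12]
    oracle = lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum())
    assert gg_epsilon(S) == pytest.approx(oracle, rel=1e-10)


def test_epsilon_and_mauchly_match_pingouin(rng):
    X = rng.normal(size=(9, 4)) * np.array([1.0, 0.5, 0.25, 0.9])
    df = pd.DataFrame(X)
    assert gg_epsilon(np.cov(X, rowvar=False)) == pytest.approx(
        pg.epsilon(df, correction="gg"), rel=1e-10)
    W, p = mauchly(X)
    ref = pg.sphericity(df)
    assert W == pytest.approx(float(ref.W), rel=1e-10)
    assert p == pytest.approx(float(ref.pval), rel=1e-8)


# -- planned tests ---------------------------------------------------------

def test_planned_contrasts_match_paired_t_oracle(rng):
    table = (_cells(rng, n_subjects=5)
             .groupby(["subject_id", "amount"])["value"].mean()
             .reset_index().rename(columns={"value": "value"}))
    amounts = [5.0, 10.0, 20.0, 40.0]
    out = planned_contrasts(table, amounts)
    assert len(out) == 3
    wide = table.pivot(index="subject_id", columns="amount", values="value")
    for res, (lo, hi) in zip(out, zip(amounts[:-1], amounts[1:])):
        d = (wide[lo] - wide[hi]).to_numpy()
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p_oracle = st.t.sf(t_oracle, len(d) - 1)
        assert res.t == pytest.approx(t_oracle, rel=1e-10)
        assert res.p_raw == pytest.approx(p_oracle, rel=1e-10)
        assert res.p_bonferroni == pytest.approx(min(1.0, 3 * p_oracle))
        assert res.p_bonferroni >= res.p_raw
        assert res.effect_r == pytest.approx(
            math.sqrt(res.t ** 2 / (res.t ** 2 + res.df)))


def test_planned_contrasts_separate_decreasing_profile(rng):
    rows = [{"subject_id": f"S{s}", "amount": a,
             "value": {5.0: 0.6, 10.0: 0.5, 20.0: 0.3, 40.0: 0.1}[a]
             + rng.normal(0, 1e-4)}
            for s in range(6) for a in (5.0, 10.0, 20.0, 40.0)]
    out = planned_contrasts(pd.DataFrame(rows), [5.0, 10.0, 20.0, 40.0])
    assert all(res.p_raw < 1e-6 for res in out)


def test_bonferroni_cap():
    rows = [{"subject_id": f"S{s}", "amount": a,
             "value": [0.1, -0.1, 0.05, -0.05][s] * a}
            for s in range(4) for a in (5.0, 10.0)]
    out = one_sample_tests(pd.DataFrame(rows), [5.0, 10.0])
    assert out[0].p_raw == pytest.approx(0.5)  # mean exactly zero, t = 0
    assert out[0].p_bonferroni == 1.0  # min(1, k * 0.5) capped


def test_one_sample_tests_family_size(rng):
    table = (_cells(rng, n_subjects=5)
             .groupby(["subject_id", "amount"])["value"].mean()
             .reset_index())
    out = one_sample_tests(table, [5.0, 10.0, 20.0, 40.0])
    for res in out:
        assert res.p_bonferroni == pytest.approx(min(1.0, 4 * res.p_raw))
        assert 0.0 <= res.p_raw <= 1.0
        assert 0.0 <= res.effect_r <= 1.0


# -- regression ------------------------------------------------------------

def test_regression_identity():
    x = np.array([1.0, 2.0, 3.0, 4.5, -1.0])
    res = trial_regression(x, x)
    assert res.r == pytest.approx(1.0)
    assert res.slope == pytest.approx(1.0)
    assert res.intercept == pytest.approx(0.0, abs=1e-12)
    assert res.df == 3


def test_regression_matches_normal_equations(rng):
    x = rng.normal(0, 5, 200)
    y = 0.219 * x + rng.normal(0, 3, 200)
    res = trial_regression(x, y)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert res.intercept == pytest.approx(beta[0], abs=1e-10)
    assert res.slope == pytest.approx(beta[1], abs=1e-10)
    assert abs(res.slope - 0.219) < 3 * 3 / (x.std() * math.sqrt(len(x)))
    assert res.df == 198


def test_regression_independent_data_is_null(rng):
    x, y = rng.normal(0, 1, 500), rng.normal(0, 1, 500)
    res = trial_regression(x, y)
    assert abs(res.r) < 0.1
    assert res.p > 0.01


def test_regression_rejects_degenerate_input():
    with pytest.raises(ValueError):
        trial_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        trial_regression([1.0, 2.0], [1.0, 2.0])


def test_aggregate_r_mean_and_se():
    res = aggregate_within_subject_r([0.2, 0.3, 0.25])
    assert res.mean == pytest.approx(0.25)
    assert res.se == pytest.approx(np.std([0.2, 0.3, 0.25], ddof=1)
                                   / math.sqrt(3))
    same = aggregate_within_subject_r([0.4, 0.4, 0.4, 0.4])
    assert same.se == 0.0


# -- Bayes factor ----------------------------------------------------------

def _bf_trapezoid(mean, se, prior_sd):
    theta = np.arange(0.0, 5.0 * prior_sd + 1e-12, 1e-4)
    prior = 2.0 * st.norm.pdf(theta, 0.0, prior_sd)
    like = st.norm.pdf(mean, theta, se)
    num = np.trapezoid(prior * like, theta)
    return num / st.norm.pdf(mean, 0.0, se)


def test_bayes_factor_matches_quadrature_oracle():
    res = dienes_bayes_factor(0.252, 0.039, 0.5)
    oracle = _bf_trapezoid(0.252, 0.039, 0.5)
    assert res.B == pytest.approx(oracle, rel=1e-4)
    assert res.B > 3  # substantial evidence at these inputs


def test_bayes_factor_null_observation_favours_null():
    assert dienes_bayes_factor(0.0, 0.1, 0.5).B < 1.0


def test_bayes_factor_monotone_in_sample_mean():
    bs = [dienes_bayes_factor(m, 0.05, 0.5).B
          for m in np.linspace(0.0, 1.0, 21)]
    assert all(b2 > b1 for b1, b2 in zip(bs, bs[1:]))


def test_bayes_factor_shrinking_se_limits():
    grow = [dienes_bayes_factor(0.3, se, 0.5).B
            for se in (0.2, 0.1, 0.05, 0.02, 0.01)]
    assert all(b2 > b1 for b1, b2 in zip(grow, grow[1:]))
    null = [dienes_bayes_factor(0.0, se, 0.5).B
            for se in (0.2, 0.1, 0.05, 0.02)]
    assert all(np.isfinite(null)) and all(b < 1 for b in null)


def test_bayes_factor_rejects_bad_se():
    with pytest.raises(ValueError):
        dienes_bayes_factor(0.2, 0.0)


# -- unimodality screen ----------------------------------------------------

def test_unimodality_screen_gaussian_and_bimodal(rng):
    rows = []
    for s in range(11):
        for a in (5.0, 10.0, 20.0, 40.0):
            for v in rng.normal(0.5, 0.2, 25):
                rows.append({"subject_id": f"S{s:02d}", "amount": a,
                             "value": v})
    out = unimodality_screen(pd.DataFrame(rows))
    assert len(out) == 44
    assert out["tenable"].sum() >= 38  # ~95% under H0 at alpha .05
    bimodal = pd.DataFrame({
        "subject_id": "S00", "amount": 5.0,
        "value": np.r_[rng.normal(0.0, 0.01, 15),
                       rng.normal(1.0, 0.01, 15)]})
    res = unimodality_screen(bimodal)
    assert not res["tenable"].iloc[0]
    tiny = unimodality_screen(pd.DataFrame(
        {"subject_id": "S00", "amount": 5.0, "value": [0.1, 0.4, 0.2]}))
    assert np.isfinite(tiny["p"].iloc[0])
    constant = unimodality_screen(pd.DataFrame(
        {"subject_id": "S00", "amount": 5.0, "value": [0.3] * 5}))
    assert constant["note"].iloc[0] == "constant sample"
    assert not constant["tenable"].iloc[0]


# -- Masson–Loftus ---------------------------------------------------------

def test_normalization_single_subject_unchanged():
    X = pd.DataFrame([[1.0, 2.0, 3.0]])
    pd.testing.assert_frame_equal(masson_loftus_normalize(X), X)


def test_normalization_removes_constant_offset():
    X = pd.DataFrame([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    norm = masson_loftus_normalize(X)
    np.testing.assert_allclose(norm.iloc[0], norm.iloc[1])
    np.testing.assert_allclose(norm.mean(axis=0), X.mean(axis=0))


def test_normalization_preserves_condition_means(rng):
    X = pd.DataFrame(rng.normal(0, 2, (5, 9)))
    norm = masson_loftus_normalize(X)
    np.testing.assert_allclose(norm.mean(axis=0), X.mean(axis=0),
                               atol=1e-12)
    gm = X.to_numpy().mean()
    np.testing.assert_allclose(norm.mean(axis=1), gm, atol=1e-12)
    with pytest.raises(ValueError, match="complete"):
        masson_loftus_normalize(X.mask(X > 10).assign(bad=np.nan))
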