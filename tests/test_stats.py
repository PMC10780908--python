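"""Tests for the mixed-model / Tukey-HSD statistics layer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import exofatigue as xf
from exofatigue.stats import MeasureModelFit, connecting_letters

MODES = ("IE", "FP", "FA", "AP")


def _balanced_df(cell_means, n_per_sex=4, subject_sd=0.0, noise_sd=0.0, seed=0):
    """20-subject-style balanced design: every subject sees all 4 modes."""
    rng = np.random.default_rng(seed)
    rows = []
    for sex in ("female", "male"):
        for i in range(n_per_sex):
            sid = f"{sex[0]}{i}"
            offset = rng.normal(0.0, subject_sd)
            for mode in MODES:
                rows.append(
                    {
                        "trial_id": f"{sid}_{mode}",
                        "subject": sid,
                        "sex": sex,
                        "mode": mode,
                        "value": cell_means[(mode, sex)]
                        + offset
                        + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


def _distinct_cells(scale=1.0):
    return {
        (m, s): scale * (10.0 * k + (1.0 if s == "male" else 0.0) + k**2)
        for k, m in enumerate(MODES)
        for s in ("female", "male")
    }


# ------------------------------------------------------ model fitting


def test_noiseless_fit_recovers_cell_means_exactly():
    cells = _distinct_cells()
    df = _balanced_df(cells, subject_sd=0.0, noise_sd=0.0)
    fit = xf.fit_measure_model(df, measure_id=10)
    for cell, mean in cells.items():
        assert fit.cell_means[cell] == pytest.approx(mean, abs=1e-8)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_pure_noise_fit_has_low_r2_and_conservative_wald():
    # No effects at all: R^2 should be small; the subject-variance Wald
    # p-value sits on a boundary null and is conservative (rejects < 5%).
    rejections, r2s = 0, []
    for rep in range(60):
        df = _balanced_df(
            {c: 0.0 for c in _distinct_cells()}, noise_sd=1.0, seed=100 + rep
        )
        fit = xf.fit_measure_model(df, measure_id=1)
        r2s.append(fit.r_squared)
        if np.isfinite(fit.wald_p) and fit.wald_p < 0.05:
            rejections += 1
    assert np.mean(r2s) < 0.6
    assert rejections / 60 <= 0.05 + 0.07


def test_strong_subject_heterogeneity_detected_by_wald():
    # Subject random-intercept SD well above residual SD, at the study's
    # design size (20 subjects x 4 modes): Wald p < 0.05 nearly always.
    # (The asymptotic Wald SE degenerates for extreme variance ratios or
    # tiny subject counts; see the methods note.)
    hits = 0
    for rep in range(100):
        df = _balanced_df(
            _distinct_cells(),
            n_per_sex=10,
            subject_sd=3.0,
            noise_sd=1.0,
            seed=200 + rep,
        )
        fit = xf.fit_measure_model(df, measure_id=1)
        if fit.wald_p < 0.05:
            hits += 1
    assert hits >= 95


def test_fit_requires_all_modes_and_two_subjects_per_sex():
    df = _balanced_df(_distinct_cells(), n_per_sex=2, noise_sd=0.1)
    with pytest.raises(ValueError):
        xf.fit_measure_model(df[df["mode"] != "AP"], measure_id=1)
    with pytest.raises(ValueError):
        xf.fit_measure_model(df[df["subject"] != "f0"].iloc[:28], measure_id=1)


# ---------------------------------------------------------- Tukey HSD


def test_connecting_letters_no_significance_is_single_letter():
    means = np.array([3.0, 2.0, 1.0, 0.5])
    sig = np.zeros((4, 4), dtype=bool)
    assert connecting_letters(means, sig) == ["A", "A", "A", "A"]


def test_connecting_letters_chain_structure():
    # 0 ~ 1, 1 ~ 2, but 0 vs 2 significant: letters A=(0,1), B=(1,2).
    means = np.array([3.0, 2.0, 1.0])
    sig = np.zeros((3, 3), dtype=bool)
    sig[0, 2] = sig[2, 0] = True
    assert connecting_letters(means, sig) == ["A", "AB", "B"]


def test_tukey_two_separated_groups_get_disjoint_letters():
    cells = {
        (m, s): (100.0 if m in ("IE", "FP") else 0.0)
        for m in MODES
        for s in ("female", "male")
    }
    df = _balanced_df(cells, noise_sd=1.0, seed=3)
    fit = xf.fit_measure_model(df, measure_id=1)
    tk = xf.tukey_hsd(fit)
    hi = {tk.letters[(m, s)] for m in ("IE", "FP") for s in ("female", "male")}
    lo = {tk.letters[(m, s)] for m in ("FA", "AP") for s in ("female", "male")}
    assert set("".join(hi)) & set("".join(lo)) == set()


def test_tukey_letters_permutation_invariant():
    df = _balanced_df(_distinct_cells(), subject_sd=1.0, noise_sd=2.0, seed=4)
    fit1 = xf.fit_measure_model(df, measure_id=1)
    shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
    fit2 = xf.fit_measure_model(shuffled, measure_id=1)
    tk1, tk2 = xf.tukey_hsd(fit1), xf.tukey_hsd(fit2)
    assert tk1.letters == tk2.letters


def test_tukey_two_group_threshold_equals_t_test():
    # q(alpha, 2, df)/sqrt(2) coincides with the two-sided t quantile.
    for df_ in (5, 20, 60, 200):
        q2 = xf.tukey_q(0.05, 2, df_)
        t2 = sps.t.ppf(1 - 0.025, df_)
        assert q2 == pytest.approx(t2, abs=1e-9)


def _brute_force_letter_cliques(sig):
    """Oracle: maximal cliques of the non-significance graph."""
    import networkx as nx

    k = sig.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                g.add_edge(i, j)
    return {frozenset(c) for c in nx.find_cliques(g)}


def _cliques_from_letters(letters):
    groups = {}
    for i, ls in enumerate(letters):
        for ch in ls:
            groups.setdefault(ch, set()).add(i)
    return {frozenset(v) for v in groups.values()}


def test_letters_match_clique_oracle_random_matrices():
    rng = np.random.default_rng(8)
    for _ in range(100):
        k = rng.integers(3, 9)
        means = rng.normal(size=k)
        sig = np.zeros((k, k), dtype=bool)
        for i in range(k):
            for j in range(i + 1, k):
                sig[i, j] = sig[j, i] = rng.random() < 0.4
        letters = connecting_letters(means, sig)
        assert _cliques_from_letters(letters) == _brute_force_letter_cliques(sig)


# ----------------------------------------------------------- summaries


def test_fit_summary_perfect_fit_and_constant_residuals():
    df = _balanced_df(_distinct_cells(), seed=5)
    fit = xf.fit_measure_model(df, measure_id=2)
    s = xf.fit_summary(fit)
    assert s.normalized_rmse_pct == pytest.approx(0.0, abs=1e-6)
    assert s.r_squared == pytest.approx(1.0, abs=1e-9)
    # constant residuals at 10% of the grand mean -> normalized RMSE 10%
    fit.resid = np.full(fit.n_obs, 0.1 * fit.data["value"].mean())
    assert xf.fit_summary(fit).normalized_rmse_pct == pytest.approx(10.0, rel=1e-9)


# -------------------------------------------------------------- ANOVA


def test_anova_identical_groups_f_zero():
    res = xf.anova_oneway(np.ones(10), ["a"] * 5 + ["b"] * 5)
    assert res.f_statistic == 0.0


def test_anova_matches_squared_t_for_two_groups():
    rng = np.random.default_rng(9)
    for _ in range(100):
        x = rng.normal(size=12)
        y = rng.normal(loc=rng.normal(), size=15)
        res = xf.anova_oneway(
            np.concatenate([x, y]), ["a"] * x.size + ["b"] * y.size
        )
        t = sps.ttest_ind(x, y, equal_var=True)
        assert res.f_statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)


def test_anova_matches_scipy_reference():
    rng = np.random.default_rng(10)
    groups = [rng.normal(loc=m, size=8) for m in (0.0, 0.4, 1.0)]
    labels = np.repeat(["a", "b", "c"], 8)
    res = xf.anova_oneway(np.concatenate(groups), labels)
    ref = sps.f_oneway(*groups)
    assert res.f_statistic == pytest.approx(ref.statistic, rel=1e-12)


def test_anova_degenerate_cases():
    res = xf.anova_oneway(
        np.array([1.0, 1.0, 2.0, 2.0]), ["a", "a", "b", "b"]
    )
    assert np.isinf(res.f_statistic) and res.degenerate
    with pytest.raises(ValueError):
        xf.anova_oneway(np.ones(3), ["a", "a", "b"])


# ------------------------------------------------------------- report


def test_report_is_deterministic(tmp_path, small_table):
    p1 = xf.report(small_table, tmp_path / "r1", measure_ids=[4, 10, 11])
    p2 = xf.report(small_table, tmp_path / "r2", measure_ids=[4, 10, 11])
    for key in ("fit_summaries", "tukey_letters"):
        assert p1[key].read_bytes() == p2[key].read_bytes()
    summary = pd.read_csv(p1["fit_summaries"])
    assert len(summary) == 3


def test_report_rejects_empty_measure_list(tmp_path, small_table):
    with pytest.raises(ValueError):
        xf.report(small_table, tmp_path, measure_ids=[])


def test_report_optional_figures(tmp_path, small_table):
    paths = xf.report(small_table, tmp_path, measure_ids=[11], figures=True)
    assert paths["fig_measure_11"].exists()
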