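"""Cohort statistics: mixed model, Tukey HSD connecting letters, reports.

Each measure is analysed with a linear mixed model

    value ~ mode + mode:sex,   random intercept per subject

(the fixed factors are the exoskeleton mode and mode-by-sex; sex itself is
not estimable as a free fixed effect because every subject contributes one
sex only, so between-subject sex variation loads on the subject random
intercept — hence the "subject Wald p-value" reported alongside each fit).

Post-hoc comparison of the eight mode-by-sex cells uses the Tukey HSD
criterion |mean_i - mean_j| > Q * SE_ij with Q = q(alpha, k, df) / sqrt(2)
from the studentized-range distribution, and connecting letters via the
insert-and-absorb algorithm: groups sharing a letter are not significantly
different.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

CELL_ORDER_MODES = ("IE", "FP", "FA", "AP")


# ---------------------------------------------------------------------------
# Mixed model per measure


@dataclass
class MeasureModelFit:
    """Fitted mode x sex model for one measure.

    ``cell_means`` maps (mode, sex) to the least-squares cell mean;
    ``cell_cov`` is the covariance of those means (fixed-effect part).
    ``method`` is "mixedlm" or, when the mixed fit is singular/degenerate,
    "ols" (cell means and R^2 still valid; subject variance unavailable).
    """

    measure_id: int
    data: pd.DataFrame
    cell_means: dict[tuple[str, str], float]
    cell_cov: np.ndarray
    cell_index: tuple[tuple[str, str], ...]
    n_obs: int
    n_subjects: int
    n_fixed: int
    resid: np.ndarray
    fitted: np.ndarray
    subject_var: float
    subject_var_se: float
    wald_p: float
    scale: float
    method: str

    @property
    def df_residual(self) -> int:
        return self.n_obs - self.n_fixed - (self.n_subjects - 1)

    @property
    def df_containment(self) -> int:
        return self.n_obs - self.n_subjects

    @property
    def r_squared(self) -> float:
        y = self.data["value"].to_numpy(dtype=float)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            return 1.0
        return 1.0 - float(np.sum(self.resid**2)) / ss_tot


def fit_measure_model(
    table, measure_id: int, channel: str | None = None
) -> MeasureModelFit:
    """Fit the random-intercept mode x sex model for one measure.

    ``table`` is an :class:`exofatigue.evaluation.MeasureTable` (or any
    object with a compatible ``values`` method, or a tidy DataFrame with
    subject/sex/mode/value columns). Requires all four modes and at least
    two subjects per sex; unbalanced missing cells proceed with a warning.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = table.values(measure_id, channel=channel)
    df = df.dropna(subset=["value"]).copy()
    modes_present = set(df["mode"])
    if not set(CELL_ORDER_MODES) <= modes_present:
        raise ValueError(f"need all 4 modes, got {sorted(modes_present)}")
    for sex in ("female", "male"):
        if df[df["sex"] == sex]["subject"].nunique() < 2:
            raise ValueError(f"need at least 2 subjects of sex {sex!r}")
    cells = df.groupby(["mode", "sex"])["value"].count()
    full = len(CELL_ORDER_MODES) * 2
    if (cells > 0).sum() < full:
        warnings.warn("unbalanced design: some mode x sex cells are empty")

    df["mode"] = pd.Categorical(df["mode"], categories=CELL_ORDER_MODES)
    cell_index = tuple(
        (m, s) for m in CELL_ORDER_MODES for s in ("female", "male")
        if ((m, s) in cells.index and cells[(m, s)] > 0)
    )
    formula = "value ~ C(mode) + C(mode):C(sex)"

    method = "mixedlm"
    design_info = None
    subject_var = subject_var_se = wald_p = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed = smf.mixedlm(formula, df, groups=df["subject"]).fit(reml=True)
        fe_names = list(mixed.fe_params.index)
        fe = mixed.fe_params.to_numpy()
        cov_fe = np.asarray(mixed.cov_params().loc[fe_names, fe_names])
        fitted = np.asarray(mixed.fittedvalues, dtype=float)
        resid = df["value"].to_numpy(dtype=float) - fitted
        scale = float(mixed.scale)
        subject_var = float(mixed.cov_re.iloc[0, 0])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # sqrt of a singular Hessian
                se = float(np.asarray(mixed.bse_re)[0])
        except Exception:
            se = np.nan
        subject_var_se = se
        if np.isfinite(se) and se > 0:
            z = subject_var / se
            wald_p = float(2.0 * sps.norm.sf(abs(z)))
        design_info = mixed.model.data.design_info
        if not np.all(np.isfinite(cov_fe)) or not np.isfinite(scale):
            raise ValueError("singular mixed fit")
    except Exception as exc:  # zero-variance / degenerate data
        log.warning(
            "measure %s: mixed model failed (%s); falling back to OLS cell means",
            measure_id, exc,
        )
        method = "ols"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(formula, df).fit()
        fe_names = list(ols.params.index)
        fe = ols.params.to_numpy()
        cov_fe = np.asarray(ols.cov_params())
        fitted = np.asarray(ols.fittedvalues, dtype=float)
        resid = np.asarray(ols.resid, dtype=float)
        scale = float(ols.mse_resid) if ols.df_resid > 0 else 0.0
        design_info = ols.model.data.design_info

    # least-squares cell means via the fixed-effect design at each cell
    from patsy import build_design_matrices

    cell_rows = pd.DataFrame(
        [{"mode": m, "sex": s, "value": 0.0} for (m, s) in cell_index]
    )
    cell_rows["mode"] = pd.Categorical(cell_rows["mode"], categories=CELL_ORDER_MODES)
    L = np.asarray(build_design_matrices([design_info], cell_rows)[0])
    means = L @ fe
    cov_cells = L @ cov_fe @ L.T

    return MeasureModelFit(
        measure_id=measure_id,
        data=df.reset_index(drop=True),
        cell_means={c: float(v) for c, v in zip(cell_index, means)},
        cell_cov=cov_cells,
        cell_index=cell_index,
        n_obs=len(df),
        n_subjects=df["subject"].nunique(),
        n_fixed=len(fe_names),
        resid=resid,
        fitted=fitted,
        subject_var=subject_var,
        subject_var_se=subject_var_se,
        wald_p=wald_p,
        scale=scale,
        method=method,
    )


# ---------------------------------------------------------------------------
# Tukey HSD with connecting letters


@dataclass
class TukeyResult:
    """All-pairs comparison of the mode x sex cells.

    ``letters`` maps each group to its connecting-letter string; groups
    sharing any letter are pairwise non-significant. ``q_critical`` is
    Q = q(alpha, k, df)/sqrt(2), the threshold on |diff| / SE_ij.
    """

    groups: tuple[tuple[str, str], ...]
    means: np.ndarray
    alpha: float
    df_denom: int
    q_critical: float
    significant: np.ndarray  # boolean (k, k)
    letters: dict[tuple[str, str], str]

    def table(self) -> pd.DataFrame:
        order = np.argsort(-self.means, kind="stable")
        rows = [
            {
                "mode": self.groups[i][0],
                "sex": self.groups[i][1],
                "letters": self.letters[self.groups[i]],
                "ls_mean": float(self.means[i]),
            }
            for i in order
        ]
        return pd.DataFrame(rows)


def tukey_q(alpha: float, k: int, df: int) -> float:
    """Critical value Q = q(alpha, k, df) / sqrt(2) of the studentized
    range, on the scale of a pairwise-difference standard error."""
    if df <= 0:
        raise ValueError("denominator df must be positive")
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df) / np.sqrt(2.0))


def connecting_letters(
    means: np.ndarray, significant: np.ndarray
) -> list[str]:
    """Insert-and-absorb connecting letters from a pairwise significance
    matrix. Returns one letter string per group (input order); groups
    sharing a letter are exactly the non-significant pairs' cliques.
    """
    k = len(means)
    cols: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            new_cols: list[set[int]] = []
            for col in cols:
                if i in col and j in col:
                    new_cols.extend([col - {i}, col - {j}])
                else:
                    new_cols.append(col)
            # absorb: drop any column contained in another
            cols = [
                c
                for idx, c in enumerate(new_cols)
                if c
                and not any(
                    c < other or (c == other and idx > jdx)
                    for jdx, other in enumerate(new_cols)
                )
            ]
    # canonical order: by best (largest) member mean, then by membership
    def col_key(c: set[int]) -> tuple:
        return (-max(means[i] for i in c), tuple(sorted(c)))

    cols.sort(key=col_key)
    letters = ["" for _ in range(k)]
    for letter_idx, col in enumerate(cols):
        ch = chr(ord("A") + letter_idx)
        for i in sorted(col):
            letters[i] += ch
    return letters


def tukey_hsd(
    fit: MeasureModelFit, alpha: float = 0.05, df_method: str = "residual"
) -> TukeyResult:
    """Tukey HSD over the mode x sex least-squares means.

    A pair differs significantly when |mean_i - mean_j| / SE_ij exceeds
    Q = q(alpha, k, df)/sqrt(2). ``df_method``: "residual" uses
    N - fixed params - (subjects - 1); "containment" uses N - subjects.
    """
    groups = fit.cell_index
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    df = fit.df_residual if df_method == "residual" else fit.df_containment
    q_crit = tukey_q(alpha, k, df)
    means = np.array([fit.cell_means[g] for g in groups])
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            var_ij = fit.cell_cov[i, i] + fit.cell_cov[j, j] - 2.0 * fit.cell_cov[i, j]
            se = np.sqrt(max(var_ij, 0.0))
            if se == 0:
                sig[i, j] = sig[j, i] = means[i] != means[j]
            else:
                sig[i, j] = sig[j, i] = abs(means[i] - means[j]) / se > q_crit
    letters = connecting_letters(means, sig)
    return TukeyResult(
        groups=groups,
        means=means,
        alpha=alpha,
        df_denom=df,
        q_critical=q_crit,
        significant=sig,
        letters={g: l for g, l in zip(groups, letters)},
    )


# ---------------------------------------------------------------------------
# Fit summary (normalized RMSE / Wald p / R^2) and one-way ANOVA


@dataclass(frozen=True)
class FitSummary:
    measure_id: int
    normalized_rmse_pct: float
    subject_wald_p: float
    r_squared: float


def fit_summary(fit: MeasureModelFit) -> FitSummary:
    """Normalized RMSE (root-mean-square residual over the grand mean, %),
    the subject-variance Wald p-value, and R^2 = 1 - SS_res/SS_tot."""
    y = fit.data["value"].to_numpy(dtype=float)
    grand = float(np.mean(y))
    rmse = float(np.sqrt(np.mean(fit.resid**2)))
    if abs(grand) < 1e-12:
        log.warning("measure %s: grand mean ~ 0, normalized RMSE undefined", fit.measure_id)
        nrmse = np.nan
    else:
        nrmse = 100.0 * rmse / abs(grand)
    return FitSummary(fit.measure_id, nrmse, fit.wald_p, fit.r_squared)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False


def anova_oneway(values: np.ndarray, labels: Sequence) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    For two groups F equals the squared pooled two-sample t statistic.
    Zero within-group variance with unequal means is flagged degenerate
    (infinite F); identical data everywhere gives F = 0.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels)
    if values.size != labels.size:
        raise ValueError("values and labels are misaligned")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    groups = [values[labels == g] for g in uniq]
    if min(len(g) for g in groups) < 2:
        raise ValueError("need at least 2 values per group")
    n = values.size
    k = len(groups)
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_between == 0:
        return AnovaResult(0.0, 1.0, df_b, df_w, degenerate=ss_within == 0)
    if ss_within == 0:
        log.warning("anova_oneway: zero within-group variance, F is infinite")
        return AnovaResult(np.inf, 0.0, df_b, df_w, degenerate=True)
    f = (ss_between / df_b) / (ss_within / df_w)
    return AnovaResult(float(f), float(sps.f.sf(f, df_b, df_w)), df_b, df_w)


# ---------------------------------------------------------------------------
# Report bundle


def report(
    table,
    outdir: str | Path,
    measure_ids: Sequence[int] | None = None,
    alpha: float = 0.05,
    df_method: str = "residual",
    figures: bool = False,
) -> dict[str, Path]:
    """Fit every measure, write fit-summary and Tukey-letter CSV tables
    (and optional per-measure bar figures) deterministically.

    Returns a name -> path mapping of the written files; identical inputs
    yield byte-identical CSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if measure_ids is None:
        measure_ids = sorted(table.df["measure_id"].unique())
    if len(measure_ids) == 0:
        raise ValueError("no measures to report")
    paths: dict[str, Path] = {}
    summaries, tukey_rows = [], []
    for mid in measure_ids:
        fit = fit_measure_model(table, mid)
        s = fit_summary(fit)
        summaries.append(
            {
                "measure_id": mid,
                "normalized_rmse_pct": s.normalized_rmse_pct,
                "subject_wald_p": s.subject_wald_p,
                "r_squared": s.r_squared,
                "fit_method": fit.method,
            }
        )
        tk = tukey_hsd(fit, alpha=alpha, df_method=df_method)
        t = tk.table()
        t.insert(0, "measure_id", mid)
        t["q_critical"] = tk.q_critical
        t["df_denom"] = tk.df_denom
        tukey_rows.append(t)
        if figures:
            paths[f"fig_measure_{mid}"] = _bar_figure(table, mid, tk, outdir)
    summary_df = pd.DataFrame(summaries)
    paths["fit_summaries"] = outdir / "fit_summaries.csv"
    summary_df.to_csv(paths["fit_summaries"], index=False, float_format="%.6g")
    tukey_df = pd.concat(tukey_rows, ignore_index=True)
    paths["tukey_letters"] = outdir / "tukey_letters.csv"
    tukey_df.to_csv(paths["tukey_letters"], index=False, float_format="%.6g")
    return paths


def _bar_figure(table, measure_id: int, tk: TukeyResult, outdir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.values(measure_id)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    stats_df = df.groupby("mode")["value"].agg(["mean", "median"])
    stats_df = stats_df.reindex([m for m in CELL_ORDER_MODES if m in stats_df.index])
    ax.bar(stats_df.index, stats_df["mean"], color="#7fa8d0")
    ax.plot(stats_df.index, stats_df["median"], "k.", ms=8, label="median")
    for sex, color in (("female", "crimson"), ("male", "navy")):
        sd = df[df["sex"] == sex].groupby("mode")["value"].std().reindex(stats_df.index)
        ax.errorbar(
            stats_df.index, stats_df["mean"], yerr=sd.to_numpy(),
            fmt="none", ecolor=color, elinewidth=1.2, capsize=3,
        )
    ax.set_title(f"Measure {measure_id}")
    ax.set_xlabel("assistance mode")
    fig.tight_layout()
    path = outdir / f"measure_{measure_id}.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
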