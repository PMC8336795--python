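"""Statistical layer: stiffness associations, Welch comparisons, marker
summaries, adhesion-array correlations and PCA projections.

Conventions: significance stars follow the usual thresholds (* p < 0.05,
** p < 0.01, *** p < 0.001); confidence intervals are t-based at 95%;
distance correlation uses the biased (original) double-centering estimator;
no multiple-testing correction is applied by default (a Benjamini-Hochberg
helper is provided but off by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA


@dataclass
class StatResult:
    name: str
    value: float
    p_value: float | None = None
    n: tuple[int, ...] | None = None
    ci: tuple[float, float] | None = None
    stars: str | None = None


def star_code(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if not 0 < p <= 1:
        raise ValueError(f"p-value {p} outside (0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Distance correlation (biased double-centering estimator), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


def stiffness_association(
    table: pd.DataFrame, feature: str, stiffness_col: str = "stiffness_kpa"
) -> dict[str, float]:
    """Spearman rho, Kendall tau and distance correlation vs stiffness.

    Rank statistics use midranks for ties.  Requires >= 10 cells spanning
    >= 2 stiffness levels; a constant feature is flagged undefined (NaNs).
    """
    x = table[stiffness_col].to_numpy(dtype=float)
    y = table[feature].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 10 or len(np.unique(x)) < 2:
        raise ValueError("need >= 10 cells spanning >= 2 stiffness levels")
    if np.ptp(y) == 0:
        warnings.warn(f"feature {feature!r} is constant; association undefined")
        return {"spearman": float("nan"), "kendall": float("nan"), "dcor": float("nan")}
    rho = float(sps.spearmanr(x, y).statistic)
    tau = float(sps.kendalltau(x, y).statistic)
    return {"spearman": rho, "kendall": tau, "dcor": distance_correlation(x, y)}


def welch_test(group_a: np.ndarray, group_b: np.ndarray) -> StatResult:
    """Unpaired two-tailed t-test with Welch's unequal-variance correction."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            # Degenerate: identical constant groups -> no evidence, p = 1.
            return StatResult("welch_t", 0.0, 1.0, (len(a), len(b)), stars="ns")
        return StatResult("welch_t", float("inf"), np.nextafter(0, 1), (len(a), len(b)), stars="***")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return StatResult("welch_t", float(t), p, (len(a), len(b)), stars=star_code(p))


def mean_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """(mean, lo, hi): t-based CI of the mean; NaN bounds for n < 2."""
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    if len(v) < 2:
        return mean, float("nan"), float("nan")
    sem = v.std(ddof=1) / np.sqrt(len(v))
    tcrit = sps.t.ppf(0.5 + level / 2, df=len(v) - 1)
    return mean, mean - tcrit * sem, mean + tcrit * sem


def summarise_marker(
    table: pd.DataFrame,
    marker: str,
    group_col: str = "stiffness_kpa",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-level mean/SD/95% CI of a marker feature plus adjacent Welch tests.

    Returns (summary, pairwise) where pairwise holds the Welch comparison of
    each pair of adjacent levels with its star code.
    """
    if marker not in table.columns:
        raise KeyError(f"marker column {marker!r} not present")
    levels = sorted(table[group_col].unique())
    rows = []
    for lev in levels:
        vals = table.loc[table[group_col] == lev, marker].dropna().to_numpy()
        mean, lo, hi = mean_ci(vals)
        rows.append(
            {
                group_col: lev,
                "n": len(vals),
                "mean": mean,
                "sd": float(vals.std(ddof=1)) if len(vals) >= 2 else float("nan"),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    summary = pd.DataFrame(rows)
    pair_rows = []
    for lo_lev, hi_lev in zip(levels[:-1], levels[1:]):
        a = table.loc[table[group_col] == lo_lev, marker].dropna().to_numpy()
        b = table.loc[table[group_col] == hi_lev, marker].dropna().to_numpy()
        res = welch_test(a, b)
        pair_rows.append(
            {
                "level_a": lo_lev,
                "level_b": hi_lev,
                "t": res.value,
                "p": res.p_value,
                "stars": res.stars,
            }
        )
    return summary, pd.DataFrame(pair_rows)


def adhesion_correlation(
    condition_table: pd.DataFrame,
    method: str = "pearson",
    protein_col: str = "protein",
    conc_col: str = "concentration",
    count_col: str = "attached",
) -> pd.DataFrame:
    """Per-protein correlation between coating concentration and cell count.

    ``method`` is ``pearson`` (default) or ``spearman``.  Proteins with a
    constant concentration are flagged undefined (NaN).  The result is ranked
    by descending correlation.
    """
    rows = []
    for protein, sub in condition_table.groupby(protein_col):
        x = sub[conc_col].to_numpy(dtype=float)
        y = sub[count_col].to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError(f"protein {protein!r} has < 3 conditions")
        if np.ptp(x) == 0:
            warnings.warn(f"protein {protein!r}: constant concentration")
            r = float("nan")
        elif method == "pearson":
            r = float(sps.pearsonr(x, y).statistic)
        elif method == "spearman":
            r = float(sps.spearmanr(x, y).statistic)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"protein": protein, "r": r, "n": len(x)})
    return (
        pd.DataFrame(rows)
        .sort_values("r", ascending=False, na_position="last")
        .reset_index(drop=True)
    )


def pca_project(
    table: pd.DataFrame, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores and explained-variance fractions.

    The input is expected z-scored; components are ordered by non-increasing
    explained variance and scores are reproducible up to sign.
    """
    X = np.asarray(table, dtype=float)
    if X.shape[0] < n_components:
        raise ValueError("fewer rows than components")
    non_const = (X.std(axis=0) > 0).sum()
    if non_const < n_components:
        raise ValueError("fewer non-constant columns than components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; raw stars are reported by default)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
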