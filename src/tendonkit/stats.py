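"""Correlation and group-comparison inference for tendon-level metrics.

The correlation analysis is a Pearson product-moment matrix over the
quantitative metrics (normalized night activity, cell alignment, angle
dispersion, cellularity) with 95% confidence intervals from the Fisher Z'
transformation, CI = tanh(atanh(r) ± 1.96/√(n−3)), and two-tailed p values
from t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom.  Missing values are
handled pairwise-complete, with n reported per pair.

Group comparisons follow the conventional battery for small-cohort
histomorphometry: D'Agostino–Pearson omnibus normality, one-way ANOVA with
Tukey HSD post hoc, and the two-tailed independent t-test (pooled Student's
by default, Welch by flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "GroupComparisonResult",
    "fisher_ci",
    "pearson_with_ci",
    "pearson_matrix",
    "correlation_frame",
    "one_way_anova_tukey",
    "independent_t_test",
    "dagostino_pearson",
    "holm_adjust",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class CorrelationResult:
    """One variable pair's Pearson correlation with Fisher Z' CI."""

    var_x: str
    var_y: str
    r: float
    n: int
    ci_low: float
    ci_high: float
    p_value: float
    degenerate: bool = False  # |r| = 1: the Fisher CI collapses to r


def fisher_ci(r: float, n: int, z: float = Z_95) -> tuple[float, float]:
    """Fisher Z' confidence interval tanh(atanh(r) ± z/√(n−3))."""
    if n - 3 <= 0:
        raise ValueError(f"need n > 3 for a Fisher CI, got n = {n}")
    if abs(r) >= 1.0:
        return (r, r)
    half = z / np.sqrt(n - 3)
    zr = np.arctanh(r)
    return float(np.tanh(zr - half)), float(np.tanh(zr + half))


def pearson_with_ci(x: np.ndarray, y: np.ndarray, var_x: str = "x",
                    var_y: str = "y") -> CorrelationResult:
    """Pearson r with Fisher CI and two-tailed p for one complete pair."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n - 3 <= 0:
        raise ValueError(f"pair ({var_x}, {var_y}): need more than 3 complete rows")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError(f"pair ({var_x}, {var_y}): a variable has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    degenerate = bool(abs(r) >= 1.0 - 1e-12)
    if degenerate:
        r = 1.0 if r > 0 else -1.0
        p = 0.0
        lo = hi = r
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        lo, hi = fisher_ci(r, n)
    return CorrelationResult(var_x, var_y, r, n, lo, hi, p, degenerate)


def pearson_matrix(table: pd.DataFrame, variables: list[str] | None = None,
                   holm: bool = False) -> list[CorrelationResult]:
    """All pairwise correlations of ``variables`` (default: all numeric
    columns), pairwise-complete.  ``holm=True`` appends Holm-adjusted p
    values as an extra attribute on each result (off by default: the
    packaged analysis reports raw p values)."""
    cols = variables or [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    results = []
    for i, cx in enumerate(cols):
        for cy in cols[i + 1:]:
            results.append(
                pearson_with_ci(table[cx].to_numpy(), table[cy].to_numpy(), cx, cy)
            )
    if holm:
        adj = holm_adjust([res.p_value for res in results])
        for res, p in zip(results, adj):
            res.p_holm = p  # type: ignore[attr-defined]
    return results


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy table of pairwise results (one row per pair)."""
    return pd.DataFrame(
        [
            {
                "var_x": r.var_x,
                "var_y": r.var_y,
                "r": r.r,
                "n": r.n,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "degenerate": r.degenerate,
                **({"p_holm": r.p_holm} if hasattr(r, "p_holm") else {}),
            }
            for r in results
        ]
    )


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


@dataclass
class GroupComparisonResult:
    """Omnibus ANOVA with Tukey HSD post hoc and per-group normality."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame = field(repr=False, default=None)
    normality: dict[str, tuple[float, float]] = field(default_factory=dict)


def one_way_anova_tukey(groups: dict[str, np.ndarray]) -> GroupComparisonResult:
    """One-way ANOVA followed by Tukey HSD over all group pairs.

    Normality (D'Agostino–Pearson K², p) is reported per group when the
    group has the minimum of 8 observations the omnibus test requires.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    for k, arr in zip(labels, arrays):
        if arr.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    f, p = sps.f_oneway(*arrays)
    res = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            lo, hi = res.confidence_interval().low[i, j], res.confidence_interval().high[i, j]
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    normality = {}
    for k, arr in zip(labels, arrays):
        if arr.size >= 8 and np.std(arr) > 0:
            k2, pn = dagostino_pearson(arr)
            normality[k] = (k2, pn)
    return GroupComparisonResult(
        f_statistic=float(f), p_value=float(p), tukey=pd.DataFrame(rows),
        normality=normality,
    )


def independent_t_test(a: np.ndarray, b: np.ndarray, welch: bool = False
                       ) -> tuple[float, float]:
    """Two-tailed independent t-test; pooled Student's unless ``welch``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not welch and np.std(a) == 0 and np.std(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def dagostino_pearson(sample: np.ndarray) -> tuple[float, float]:
    """D'Agostino–Pearson omnibus normality test (K², p from χ²₂).

    K² combines the standardized skewness and kurtosis statistics; the test
    needs at least 8 observations and nonzero variance.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError(f"omnibus normality test needs n >= 8, got {x.size}")
    if np.std(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    k2, p = sps.normaltest(x)
    return float(k2), float(p)
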