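"""Model-comparison hypothesis tests and adaptive step-down FDR control.

Pairwise model comparisons on the rate metrics (sensitivity, specificity,
PPV, NPV) are Pearson chi-square tests, without continuity correction, on the
2x2 success/failure table built from each model's confusion counts over the
metric's own denominator. One-tailed p-values follow the direction-halving
rule: p/2 when the observed difference is in the hypothesized direction,
1 - p/2 otherwise.

Multiplicity is handled by the Gavrilov–Benjamini–Sarkar optimal adaptive
step-down procedure with critical constants

    c_k = k·α / (m + 1 − k·(1 − α)),   k = 1..m,

applied to the increasingly sorted p-values: the largest prefix with
p_(i) ≤ c_i for every i ≤ k is rejected. Adjusted p-values are the smallest
α at which each sorted p-value would be rejected (monotone-enforced in
sorted order); at m = 1 the procedure reduces to rejecting p ≤ α/(1+α).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .metrics import ConfusionCounts

__all__ = [
    "HypothesisResult",
    "chi_square_compare",
    "gavrilov_critical_values",
    "gavrilov_adjust",
    "adjust_results",
]

RATE_METRIC_TABLES = {
    # metric -> (successes, failures) attribute names on ConfusionCounts
    "sensitivity": ("tp", "fn"),
    "specificity": ("tn", "fp"),
    "ppv": ("tp", "fp"),
    "npv": ("tn", "fn"),
}


@dataclass
class HypothesisResult:
    """One tested hypothesis with raw and (once adjusted) FDR-corrected p."""

    hypothesis_id: str
    family: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    rejected_at_alpha: bool | None = None
    defined: bool = True
    detail: dict = field(default_factory=dict)


def _pearson_chi2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square statistic and upper-tail p for a 2x2 table.

    Degenerate margins (an all-zero row or column, i.e. no variation) give
    statistic 0 and p = 1.
    """
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        return 0.0, 1.0
    expected = row @ col / total
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def chi_square_compare(c1: ConfusionCounts, c2: ConfusionCounts, metric: str,
                       tails: str = "two",
                       hypothesis_id: str = "",
                       family: str = "model_vs_model_2tailed") -> HypothesisResult:
    """Chi-square comparison of one rate metric between two classifiers.

    ``tails='one'`` tests the directional hypothesis that group 1's success
    proportion exceeds group 2's. A zero denominator in either group yields
    an undefined result rather than an exception.
    """
    if metric not in RATE_METRIC_TABLES:
        raise ValueError(
            f"chi-square comparison is defined for rate metrics {sorted(RATE_METRIC_TABLES)}, "
            f"got {metric!r}")
    if tails not in ("one", "two"):
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    s_attr, f_attr = RATE_METRIC_TABLES[metric]
    s1, f1 = getattr(c1, s_attr), getattr(c1, f_attr)
    s2, f2 = getattr(c2, s_attr), getattr(c2, f_attr)
    hid = hypothesis_id or f"{metric}:{tails}-tailed"
    if s1 + f1 == 0 or s2 + f2 == 0:
        return HypothesisResult(hid, family, math.nan, math.nan, defined=False,
                                detail={"metric": metric, "reason": "zero denominator"})
    stat, p_two = _pearson_chi2(np.array([[s1, f1], [s2, f2]]))
    if tails == "two":
        p = p_two
    else:
        in_direction = s1 / (s1 + f1) > s2 / (s2 + f2)
        p = p_two / 2 if in_direction else 1 - p_two / 2
    return HypothesisResult(hid, family, stat, p,
                            detail={"metric": metric, "table": [[s1, f1], [s2, f2]],
                                    "tails": tails})


def gavrilov_critical_values(m: int, alpha: float) -> np.ndarray:
    """Step-down critical constants c_k = kα/(m+1−k(1−α)) for k = 1..m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    k = np.arange(1, m + 1, dtype=float)
    return k * alpha / (m + 1 - k * (1 - alpha))


def gavrilov_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive step-down FDR adjustment.

    Returns ``(p_adjusted, rejected)`` in the original input order. The
    adjusted value for the k-th sorted p is the smallest α at which the
    step-down procedure would reject it, i.e. the running maximum over
    i ≤ k of p_(i)·(m+1−i)/(i·(1−p_(i))), clipped to 1; rejection at level
    ``alpha`` is p_adjusted ≤ alpha, which reproduces the largest prefix
    with p_(i) ≤ c_i for all i ≤ k.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    k = np.arange(1, m + 1, dtype=float)
    with np.errstate(divide="ignore"):
        alpha_k = np.where(
            p_sorted < 1.0,
            p_sorted * (m + 1 - k) / (k * (1.0 - p_sorted)),
            np.inf,
        )
    adj_sorted = np.minimum(np.maximum.accumulate(alpha_k), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    rejected = adjusted <= alpha
    return adjusted, rejected


def adjust_results(results: list[HypothesisResult],
                   alpha: float = 0.05) -> list[HypothesisResult]:
    """FDR-adjust a family of HypothesisResults in place (undefined ones skipped)."""
    defined = [r for r in results if r.defined]
    if defined:
        adjusted, rejected = gavrilov_adjust([r.p_raw for r in defined], alpha)
        for r, pa, rej in zip(defined, adjusted, rejected):
            r.p_adjusted = float(pa)
            r.rejected_at_alpha = bool(rej)
    return results
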