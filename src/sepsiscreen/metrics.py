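"""Evaluation metrics with the study's confidence-interval constructions.

Discrimination is measured by sensitivity, specificity, PPV, NPV (Wald CIs on
the appropriate denominator), AUC and average PPV (Wald-form CIs around the
point estimate using a Hanley–McNeil standard error); calibration by the
Brier score (Hoeffding-inequality CI, distribution-free); utility by the
standardized net benefit sNB = NB/π at a fixed decision threshold.

AUC is the Mann–Whitney statistic P(score+ > score-) + 0.5·P(tie). Average
PPV is step-wise average precision with ties resolved exactly in expectation
over all orderings of tied blocks (a hypergeometric order-statistic closed
form), so it is deterministic and matches a brute-force permutation average.

A metric whose denominator is empty is reported with ``defined=False`` and
NaN fields, never as a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricEstimate",
    "confusion",
    "rate_metrics",
    "auc",
    "average_ppv",
    "brier",
    "snb",
    "standard_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts for binary decisions (abstentions excluded upstream)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.n


@dataclass(frozen=True)
class MetricEstimate:
    """A named metric value with its CI, CI method and sample quantities."""

    name: str
    value: float
    ci_low: float
    ci_high: float
    ci_method: str  # wald | riley_se | hoeffding | none
    alpha: float
    n: int
    defined: bool = True

    @staticmethod
    def undefined(name: str, alpha: float, n: int = 0) -> "MetricEstimate":
        return MetricEstimate(name, math.nan, math.nan, math.nan, "none", alpha, n, False)

    def as_dict(self) -> dict:
        return {
            "metric": self.name,
            "value": None if not self.defined else self.value,
            "ci": None if not self.defined else [self.ci_low, self.ci_high],
            "ci_method": self.ci_method,
            "n": self.n,
            "defined": self.defined,
        }


def confusion(decisions, labels) -> ConfusionCounts:
    """Exact confusion counts from binary decisions (1 = sepsis) and labels."""
    decisions = np.asarray(decisions)
    labels = np.asarray(labels)
    if decisions.shape != labels.shape:
        raise ValueError(f"length mismatch: {decisions.shape} vs {labels.shape}")
    if decisions.size == 0:
        raise ValueError("empty input")
    d = decisions.astype(int)
    y = labels.astype(int)
    return ConfusionCounts(
        tp=int(((d == 1) & (y == 1)).sum()),
        fp=int(((d == 1) & (y == 0)).sum()),
        tn=int(((d == 0) & (y == 0)).sum()),
        fn=int(((d == 0) & (y == 1)).sum()),
    )


def _wald(name: str, successes: int, denominator: int, alpha: float) -> MetricEstimate:
    if denominator == 0:
        return MetricEstimate.undefined(name, alpha)
    p = successes / denominator
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(p * (1 - p) / denominator)
    return MetricEstimate(
        name, p, max(0.0, p - half), min(1.0, p + half), "wald", alpha, denominator,
    )


def rate_metrics(c: ConfusionCounts, alpha: float = 0.05) -> dict[str, MetricEstimate]:
    """Sensitivity, specificity, PPV and NPV with Wald CIs.

    Each CI is p ± z_{α/2}·sqrt(p(1−p)/n) on the metric's own denominator,
    clipped to [0, 1]; an empty denominator yields ``defined=False``.
    """
    return {
        "sensitivity": _wald("sensitivity", c.tp, c.tp + c.fn, alpha),
        "specificity": _wald("specificity", c.tn, c.tn + c.fp, alpha),
        "ppv": _wald("ppv", c.tp, c.tp + c.fp, alpha),
        "npv": _wald("npv", c.tn, c.tn + c.fn, alpha),
    }


def _hanley_mcneil_se(v: float, n_pos: int, n_neg: int) -> float:
    # SE for a rank statistic v in [0,1]; Q1 = v/(2-v), Q2 = 2v^2/(1+v).
    q1 = v / (2 - v)
    q2 = 2 * v * v / (1 + v)
    num = v * (1 - v) + (n_pos - 1) * (q1 - v * v) + (n_neg - 1) * (q2 - v * v)
    return math.sqrt(max(num, 0.0) / (n_pos * n_neg))


def _riley_ci(name, v, n_pos, n_neg, alpha, lo_clip=0.0, hi_clip=1.0) -> MetricEstimate:
    z = stats.norm.ppf(1 - alpha / 2)
    se = _hanley_mcneil_se(min(max(v, 0.0), 1.0), max(n_pos, 1), max(n_neg, 1))
    lo, hi = v - z * se, v + z * se
    if lo_clip is not None:
        lo = max(lo_clip, lo)
    if hi_clip is not None:
        hi = min(hi_clip, hi)
    return MetricEstimate(name, v, lo, hi, "riley_se", alpha, n_pos + n_neg)


def auc(scores, labels, alpha: float = 0.05) -> MetricEstimate:
    """Mann–Whitney AUC with a Wald-form CI on a Hanley–McNeil SE.

    Undefined when only one class is present. Ties contribute 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return MetricEstimate.undefined("auc", alpha, labels.size)
    ranks = stats.rankdata(scores)  # midranks: ties get 1/2 weight
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    v = u / (n_pos * n_neg)
    return _riley_ci("auc", v, n_pos, n_neg, alpha)


def _block_expected_precision_sum(b: int, bp: int, g: int, gp: int) -> float:
    """Expected sum of precisions at the positives of one tied block.

    The block holds g tied items, gp of them positive, preceded by b items of
    which bp are positive. Under a uniformly random ordering of the block the
    k-th block positive sits at within-block position i with probability
    C(i-1, k-1)·C(g-i, gp-k)/C(g, gp), giving precision (bp+k)/(b+i).
    """
    if gp == 0:
        return 0.0
    denom = math.comb(g, gp)
    total = 0.0
    gn = g - gp
    for k in range(1, gp + 1):
        for i in range(k, k + gn + 1):
            w = math.comb(i - 1, k - 1) * math.comb(g - i, gp - k)
            total += (bp + k) / (b + i) * (w / denom)
    return total


def average_ppv(scores, labels, alpha: float = 0.05) -> MetricEstimate:
    """Average precision over positives ranked by descending score (A-PPV).

    Tied scores are handled exactly in expectation over the orderings of each
    tied block. Undefined with no positives.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0:
        return MetricEstimate.undefined("a_ppv", alpha, labels.size)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    total = 0.0
    b = bp = 0
    start = 0
    while start < len(s):
        stop = start
        while stop < len(s) and s[stop] == s[start]:
            stop += 1
        g = stop - start
        gp = int(y[start:stop].sum())
        total += _block_expected_precision_sum(b, bp, g, gp)
        b += g
        bp += gp
        start = stop
    v = total / n_pos
    return _riley_ci("a_ppv", v, n_pos, max(n_neg, 1), alpha)


def brier(scores, labels, alpha: float = 0.05) -> MetricEstimate:
    """Mean squared error between confidence score and outcome.

    CI from the Hoeffding inequality for a bounded mean: half-width
    sqrt(ln(2/α)/(2n)), clipped to [0, 1]. Distribution-free and conservative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.size == 0:
        return MetricEstimate.undefined("brier", alpha)
    n = scores.size
    value = float(np.mean((scores - labels) ** 2))
    half = math.sqrt(math.log(2 / alpha) / (2 * n))
    return MetricEstimate(
        "brier", value, max(0.0, value - half), min(1.0, value + half),
        "hoeffding", alpha, n,
    )


def snb(c: ConfusionCounts, decision_threshold: float = 0.5,
        alpha: float = 0.05) -> MetricEstimate:
    """Standardized net benefit at a fixed decision threshold t.

    NB = sens·π − (1−spec)·(1−π)·t/(1−t); sNB = NB/π. Undefined at π = 0.
    The CI reuses the Hanley–McNeil SE evaluated at sNB clipped into [0,1];
    only the upper end of the interval is clipped (at 1) since sNB can be
    negative.
    """
    t = decision_threshold
    if not 0.0 < t < 1.0:
        raise ValueError(f"decision_threshold must be in (0,1), got {t}")
    n_pos = c.tp + c.fn
    n_neg = c.tn + c.fp
    if n_pos == 0:
        return MetricEstimate.undefined("snb", alpha, c.n)
    pi = n_pos / c.n
    sens = c.tp / n_pos
    spec = c.tn / n_neg if n_neg else 1.0
    nb = sens * pi - (1 - spec) * (1 - pi) * (t / (1 - t))
    v = nb / pi
    return _riley_ci("snb", v, n_pos, max(n_neg, 1), alpha, lo_clip=None, hi_clip=1.0)


def standard_metrics(scores, labels, threshold: float = 0.5,
                     snb_threshold: float = 0.5,
                     alpha: float = 0.05) -> dict[str, MetricEstimate]:
    """The full metric panel for a score vector at a hard decision threshold.

    Decisions are score ≥ threshold; returns sensitivity, specificity, PPV,
    NPV, AUC, A-PPV, Brier and sNB keyed by name.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    c = confusion((scores >= threshold).astype(int), labels)
    out = rate_metrics(c, alpha)
    out["auc"] = auc(scores, labels, alpha)
    out["a_ppv"] = average_ppv(scores, labels, alpha)
    out["brier"] = brier(scores, labels, alpha)
    out["snb"] = snb(c, snb_threshold, alpha)
    return out
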