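"""Cautious (abstaining) classification over confidence scores.

A cautious classifier commits only when a model's sepsis-confidence score is
extreme: score ≥ th → sepsis, score ≤ 1−th → no sepsis, anything strictly
inside (1−th, th) → abstain. With the default th = 0.75 the abstention region
is the open interval (0.25, 0.75). Performance on the committed ("high
confidence", HC) subset is reported alongside the coverage, the fraction of
cases not abstained upon.

Also implemented here is the two-feature partial decision rule (PDR) derived
from an interpretable decision tree over MDW and neutrophils:

    MDW > 24.1                         → sepsis
    MDW ≤ 24.1 and neutrophils ≤ 8.6   → no sepsis
    MDW ≤ 20.5 and neutrophils > 8.6   → no sepsis
    otherwise (20.5 < MDW ≤ 24.1 and neutrophils > 8.6) → abstain
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import MetricEstimate, confusion, rate_metrics, auc, average_ppv, brier, snb

__all__ = [
    "SEPSIS",
    "NO_SEPSIS",
    "ABSTAIN",
    "CautiousConfig",
    "CautiousResult",
    "cautious_predict",
    "pdr_predict",
    "pdr_predict_table",
    "coverage",
    "hc_evaluate",
]

SEPSIS = "sepsis"
NO_SEPSIS = "no_sepsis"
ABSTAIN = "abstain"

PDR_MDW_UPPER = 24.1
PDR_MDW_LOWER = 20.5
PDR_NEUTROPHILS = 8.6


@dataclass(frozen=True)
class CautiousConfig:
    """Upper confidence threshold th ∈ (0.5, 1]; lower bound is 1−th."""

    th: float = 0.75

    def __post_init__(self) -> None:
        if not 0.5 < self.th <= 1.0:
            raise ValueError(f"th must be in (0.5, 1], got {self.th}")


@dataclass
class CautiousResult:
    """Decisions, coverage, and the metric panel on the committed subset."""

    decisions: np.ndarray
    coverage: float
    hc_metrics: dict[str, MetricEstimate]


def cautious_predict(scores, config: CautiousConfig = CautiousConfig()) -> np.ndarray:
    """Three-region thresholding of confidence scores.

    score ≥ th → sepsis; score ≤ 1−th → no sepsis; otherwise abstain.
    Scores must lie in [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size and (np.nanmin(scores) < 0 or np.nanmax(scores) > 1 or np.isnan(scores).any()):
        raise ValueError("scores must lie in [0, 1]")
    out = np.full(scores.shape, ABSTAIN, dtype=object)
    out[scores >= config.th] = SEPSIS
    out[scores <= 1 - config.th] = NO_SEPSIS
    return out


def pdr_predict(mdw: float, neutrophils: float) -> str:
    """The printed PDR rules for a single case; inputs must be observed."""
    for name, v in (("mdw", mdw), ("neutrophils", neutrophils)):
        if v is None or not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be a finite non-negative number, got {v!r}")
    if mdw > PDR_MDW_UPPER:
        return SEPSIS
    if neutrophils <= PDR_NEUTROPHILS:  # here MDW ≤ 24.1
        return NO_SEPSIS
    if mdw <= PDR_MDW_LOWER:
        return NO_SEPSIS
    return ABSTAIN


def pdr_predict_table(table) -> np.ndarray:
    """Vectorized PDR over a FeatureTable; errors on masked MDW/neutrophil cells."""
    for name in ("mdw", "neutrophils"):
        if table.column_mask(name).any():
            raise ValueError(f"masked {name} cells present; impute first")
    mdw = table.column("mdw")
    neut = table.column("neutrophils")
    out = np.full(table.n, ABSTAIN, dtype=object)
    out[mdw > PDR_MDW_UPPER] = SEPSIS
    out[(mdw <= PDR_MDW_UPPER) & (neut <= PDR_NEUTROPHILS)] = NO_SEPSIS
    out[(mdw <= PDR_MDW_LOWER) & (neut > PDR_NEUTROPHILS)] = NO_SEPSIS
    return out


def coverage(decisions) -> float:
    """Exact fraction of non-abstain decisions."""
    decisions = np.asarray(decisions, dtype=object)
    if decisions.size == 0:
        raise ValueError("empty decision vector")
    return float((decisions != ABSTAIN).sum() / decisions.size)


def hc_evaluate(scores, labels, config: CautiousConfig = CautiousConfig(),
                snb_threshold: float = 0.5, alpha: float = 0.05) -> CautiousResult:
    """Cautious decisions plus the high-confidence metric panel.

    All metrics are computed on the committed rows only; rank metrics (AUC,
    A-PPV, Brier) use the committed rows' raw scores. Metrics whose
    denominator is empty on the committed subset come back ``defined=False``;
    with an empty committed subset the coverage is 0 and every metric is
    undefined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores/labels length mismatch")
    decisions = cautious_predict(scores, config)
    covered = decisions != ABSTAIN
    cov = float(covered.sum() / len(decisions)) if len(decisions) else 0.0
    names = ("sensitivity", "specificity", "ppv", "npv", "auc", "a_ppv", "brier", "snb")
    if not covered.any():
        hc = {m: MetricEstimate.undefined(m, alpha) for m in names}
        return CautiousResult(decisions=decisions, coverage=0.0, hc_metrics=hc)
    s_cov = scores[covered]
    y_cov = labels[covered]
    d_cov = (decisions[covered] == SEPSIS).astype(int)
    c = confusion(d_cov, y_cov)
    hc = rate_metrics(c, alpha)
    hc["auc"] = auc(s_cov, y_cov, alpha)
    hc["a_ppv"] = average_ppv(s_cov, y_cov, alpha)
    hc["brier"] = brier(s_cov, y_cov, alpha)
    hc["snb"] = snb(c, snb_threshold, alpha)
    return CautiousResult(decisions=decisions, coverage=cov, hc_metrics=hc)
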