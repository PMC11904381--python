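"""Random-forest regression imputation of the MDW feature.

MDW is only reported by one vendor's hematology analyzers, so whole cohorts
can lack it (a missingness shift). The imputer is a random-forest regressor
trained on the pooled rows of cohorts where MDW was observed, with every
other feature (but never the label) as predictor. Goodness of fit is
assessed on a held-out 25% of the pooled training rows by the adjusted R²

    adj R² = 1 − (1 − R²)·(n − 1)/(n − p − 1),

and the assessed model is then applied to fill the masked MDW cells of a
target cohort, leaving observed cells untouched.

"Default hyperparameters" are pinned (100 trees, unlimited depth, all
features considered at every split — the library default for regression
forests — and a fixed seed) so results are stable across library versions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split

from .cohorts import FEATURE_NAMES, FeatureTable

__all__ = [
    "ImputerModel",
    "ImputationEvaluation",
    "adjusted_r2",
    "fit_imputer",
    "evaluate_imputer",
    "impute_feature",
]

TARGET = "mdw"
PREDICTORS: tuple[str, ...] = tuple(f for f in FEATURE_NAMES if f != TARGET)

_RF_DEFAULTS = dict(n_estimators=100, max_depth=None, max_features=1.0, n_jobs=1)


@dataclass
class ImputerModel:
    """Fitted MDW regressor; MDW and the sepsis label are never predictors."""

    predictors: tuple[str, ...]
    fitted_state: RandomForestRegressor
    training_cohorts: tuple[str, ...]

    def predict(self, table: FeatureTable) -> np.ndarray:
        cols = [table.column_index(f) for f in self.predictors]
        masked = table.mask[:, cols]
        if masked.any():
            rows = np.nonzero(masked.any(axis=1))[0]
            raise ValueError(f"masked predictor cells in rows {rows[:20].tolist()}")
        pred = self.fitted_state.predict(table.values[:, cols])
        return np.maximum(pred, 0.0)


@dataclass(frozen=True)
class ImputationEvaluation:
    """Hold-out fit quality of the imputer."""

    r2: float
    adjusted_r2: float
    n_eval: int
    p_predictors: int


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 − (1 − R²)(n − 1)/(n − p − 1); requires n > p + 1."""
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _pooled_observed(tables: list[FeatureTable]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled predictor matrix and MDW targets over rows with MDW observed."""
    xs, ys = [], []
    cols = [FEATURE_NAMES.index(f) for f in PREDICTORS]
    j_t = FEATURE_NAMES.index(TARGET)
    for t in tables:
        ok = ~t.mask[:, j_t] & ~t.mask[:, cols].any(axis=1)
        if ok.any():
            xs.append(t.values[np.nonzero(ok)[0]][:, cols])
            ys.append(t.values[np.nonzero(ok)[0], j_t])
    if not xs:
        raise ValueError("no rows with observed MDW in the supplied tables")
    return np.vstack(xs), np.concatenate(ys)


def fit_imputer(tables: list[FeatureTable], seed: int = 0,
                cohort_ids: tuple[str, ...] = ()) -> ImputerModel:
    """Fit the random-forest MDW regressor on pooled observed rows.

    Rows are concatenated across cohorts with no reweighting; at least 50
    usable rows are required. Deterministic given ``seed``.
    """
    x, y = _pooled_observed(tables)
    if len(y) < 50:
        raise ValueError(f"need >= 50 rows with observed MDW, got {len(y)}")
    rf = RandomForestRegressor(random_state=seed, **_RF_DEFAULTS)
    rf.fit(x, y)
    return ImputerModel(predictors=PREDICTORS, fitted_state=rf,
                        training_cohorts=tuple(cohort_ids))


def evaluate_imputer(tables: list[FeatureTable], fraction: float = 0.75,
                     seed: int = 0) -> ImputationEvaluation:
    """75/25 hold-out evaluation of the imputer on the pooled rows.

    Fits on the ``fraction`` share, reports R² and adjusted R² between
    predicted and true MDW on the remainder. The evaluation rows are disjoint
    from the fitting rows by construction.
    """
    x, y = _pooled_observed(tables)
    if len(y) < 50:
        raise ValueError(f"need >= 50 rows with observed MDW, got {len(y)}")
    x_tr, x_ev, y_tr, y_ev = train_test_split(
        x, y, train_size=fraction, random_state=seed, shuffle=True)
    p = len(PREDICTORS)
    if len(y_ev) < p + 2:
        raise ValueError(
            f"evaluation split of {len(y_ev)} rows too small for adjusted R^2 with {p} predictors")
    rf = RandomForestRegressor(random_state=seed, **_RF_DEFAULTS)
    rf.fit(x_tr, y_tr)
    r2 = float(r2_score(y_ev, rf.predict(x_ev)))
    return ImputationEvaluation(
        r2=r2, adjusted_r2=adjusted_r2(r2, len(y_ev), p),
        n_eval=len(y_ev), p_predictors=p)


def impute_feature(model: ImputerModel, table: FeatureTable) -> FeatureTable:
    """Fill masked MDW cells with model predictions; observed cells untouched.

    Returns a copy with the mask cleared on the filled cells; imputing a
    table with no masked MDW is a no-op (idempotence).
    """
    j_t = table.column_index(TARGET)
    out = table.copy()
    missing = out.mask[:, j_t]
    if not missing.any():
        return out
    rows = np.nonzero(missing)[0]
    pred = model.predict(table.subset(rows))
    out.values[rows, j_t] = pred
    out.mask[rows, j_t] = False
    return out
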