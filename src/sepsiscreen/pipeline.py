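"""Tuned 3-step classification pipelines and fixed-threshold baselines.

Every model is a scikit-learn pipeline of (1) a feature scaling step, (2)
recursive feature elimination (RFE) scored by the absolute coefficients of a
logistic model, one feature dropped per iteration, and (3) the classifier.
Five families are supported: logistic regression, linear SVM (with a sigmoid
probability calibration wrapper so margins become confidence scores in
[0, 1]), random forest, gradient-boosted trees (XGBoost) and a single
decision tree. Hyperparameters are tuned by randomized search over the
documented per-family grids, scored by mean AUC over stratified k-fold
cross-validation; ties go to the earliest trial, so the search is
deterministic given its seed.

Missing values are a hard error at fit and predict time: imputation is an
explicit upstream stage (see :mod:`sepsiscreen.imputation`), never something
the pipeline does silently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, RobustScaler, StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .cautious import NO_SEPSIS, SEPSIS
from .cohorts import FEATURE_NAMES, FeatureTable
from .metrics import auc

__all__ = [
    "MODEL_FAMILIES",
    "PipelineConfig",
    "TrainedModel",
    "SearchResult",
    "split_train_test",
    "sample_config",
    "tune_hyperparameters",
    "fit",
    "predict_scores",
    "threshold_baseline",
]

MODEL_FAMILIES = (
    "logistic_regression",
    "linear_svm",
    "random_forest",
    "gradient_boosted_trees",
    "decision_tree",
)

SCALERS = ("standard", "minmax", "robust", "none")

# Shared search dimensions (scaler and feature count are pipeline-level
# hyperparameters common to every family).
_N_FEATURES_GRID = (5, 8, 10, 12, 15, 19)
_CLASS_WEIGHT_GRID = ("none", "balanced")
_C_GRID = tuple(10.0 ** e for e in range(-4, 5))  # 1e-4 .. 1e4
_DEPTH_GRID = tuple(range(2, 13))
_N_ESTIMATORS_GRID = (50, 100, 200, 400)
_LEARNING_RATE_GRID = (0.01, 0.05, 0.1, 0.3)
_MIN_LEAF_GRID = (1, 5, 10, 20)

#: Documented randomized-search grid per model family.
FAMILY_GRIDS: dict[str, dict[str, tuple]] = {
    "logistic_regression": {"C": _C_GRID},
    "linear_svm": {"C": _C_GRID},
    "random_forest": {"n_estimators": _N_ESTIMATORS_GRID, "max_depth": _DEPTH_GRID},
    "gradient_boosted_trees": {
        "n_estimators": _N_ESTIMATORS_GRID,
        "max_depth": _DEPTH_GRID,
        "learning_rate": _LEARNING_RATE_GRID,
    },
    "decision_tree": {"max_depth": _DEPTH_GRID, "min_samples_leaf": _MIN_LEAF_GRID},
}


@dataclass(frozen=True)
class PipelineConfig:
    """One fully specified 3-step pipeline configuration."""

    model_family: str
    scaler: str = "standard"
    n_features_selected: int = 19
    class_weighting: str = "none"
    family_hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.model_family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model_family {self.model_family!r}")
        if self.scaler not in SCALERS:
            raise ValueError(f"unknown scaler {self.scaler!r}")
        if not 1 <= self.n_features_selected <= len(FEATURE_NAMES):
            raise ValueError(
                f"n_features_selected must be in [1, {len(FEATURE_NAMES)}], "
                f"got {self.n_features_selected}")
        if self.class_weighting not in _CLASS_WEIGHT_GRID:
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")
        grid = FAMILY_GRIDS[self.model_family]
        for key in self.family_hyperparameters:
            if key not in grid:
                raise ValueError(
                    f"hyperparameter {key!r} not in the {self.model_family} grid "
                    f"({sorted(grid)})")


@dataclass
class TrainedModel:
    """A fitted pipeline with its configuration and selection record."""

    config: PipelineConfig
    selected_features: tuple[str, ...]
    fitted_state: Pipeline
    training_summary: dict


@dataclass
class SearchResult:
    """Randomized-search outcome: the winning config plus every trial."""

    best_config: PipelineConfig
    trials: list  # (config, fold_aucs, mean_auc)


# --------------------------------------------------------------------------
# Splitting
# --------------------------------------------------------------------------

def split_train_test(table: FeatureTable, fraction: float = 0.75,
                     seed: int = 0) -> tuple[FeatureTable, FeatureTable]:
    """Stratified row-disjoint partition preserving the sepsis proportion.

    ``fraction`` is the training share. Per-split class counts differ from
    exact proportionality by at most one case. Single-class input is an error.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    y = table.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to stratify the split")
    idx = np.arange(table.n)
    train_idx, test_idx = train_test_split(
        idx, train_size=fraction, stratify=y, random_state=seed, shuffle=True)
    return table.subset(np.sort(train_idx)), table.subset(np.sort(test_idx))


# --------------------------------------------------------------------------
# Randomized search
# --------------------------------------------------------------------------

def sample_config(family: str, rng: np.random.Generator, seed: int = 0) -> PipelineConfig:
    """Draw one configuration uniformly from the family's documented grid."""
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model_family {family!r}")
    grid = FAMILY_GRIDS[family]
    hp = {k: v[rng.integers(len(v))] for k, v in sorted(grid.items())}
    return PipelineConfig(
        model_family=family,
        scaler=SCALERS[rng.integers(len(SCALERS))],
        n_features_selected=int(_N_FEATURES_GRID[rng.integers(len(_N_FEATURES_GRID))]),
        class_weighting=_CLASS_WEIGHT_GRID[rng.integers(len(_CLASS_WEIGHT_GRID))],
        family_hyperparameters=hp,
        seed=seed,
    )


def tune_hyperparameters(train: FeatureTable, family: str, budget: int = 1000,
                         k: int = 5, seed: int = 0) -> SearchResult:
    """Randomized search scored by mean AUC over stratified k-fold CV.

    Samples ``budget`` configurations uniformly from the family grid and
    returns the argmax of the mean fold AUC, ties broken by earliest trial.
    Deterministic given ``seed``. Requires at least ``k`` positive cases so
    every stratified fold contains both classes.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if k < 2:
        raise ValueError("k must be >= 2")
    n_pos = int((train.labels == 1).sum())
    if n_pos < k:
        raise ValueError(
            f"stratified {k}-fold CV impossible with only {n_pos} positive cases")
    _check_observed(train, "tune_hyperparameters")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(train.values, train.labels))
    trials = []
    best_i, best_mean = 0, -np.inf
    for i in range(budget):
        config = sample_config(family, rng, seed=seed)
        fold_aucs = []
        for tr_idx, va_idx in folds:
            model = fit(config, train.subset(tr_idx))
            scores = predict_scores(model, train.subset(va_idx))
            fold_aucs.append(auc(scores, train.labels[va_idx]).value)
        mean_auc = float(np.mean(fold_aucs))
        trials.append((config, fold_aucs, mean_auc))
        if mean_auc > best_mean:  # strict: first trial achieving the max wins
            best_i, best_mean = i, mean_auc
    return SearchResult(best_config=trials[best_i][0], trials=trials)


# --------------------------------------------------------------------------
# Fitting and scoring
# --------------------------------------------------------------------------

def _make_scaler(name: str):
    return {
        "standard": StandardScaler(),
        "minmax": MinMaxScaler(),
        "robust": RobustScaler(),
        "none": "passthrough",
    }[name]


def _make_classifier(config: PipelineConfig, y: np.ndarray):
    hp = config.family_hyperparameters
    cw = "balanced" if config.class_weighting == "balanced" else None
    seed = config.seed
    family = config.model_family
    if family == "logistic_regression":
        return LogisticRegression(C=hp.get("C", 1.0), class_weight=cw,
                                  max_iter=2000, random_state=seed)
    if family == "linear_svm":
        base = LinearSVC(C=hp.get("C", 1.0), class_weight=cw, random_state=seed,
                         max_iter=5000, dual="auto")
        # sigmoid calibration fitted in-fold turns margins into confidences
        return CalibratedClassifierCV(base, method="sigmoid", cv=3)
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100), max_depth=hp.get("max_depth"),
            class_weight=cw, random_state=seed, n_jobs=1)
    if family == "gradient_boosted_trees":
        n_pos = int((y == 1).sum())
        n_neg = int((y == 0).sum())
        spw = (n_neg / max(n_pos, 1)) if config.class_weighting == "balanced" else 1.0
        return XGBClassifier(
            n_estimators=hp.get("n_estimators", 100), max_depth=hp.get("max_depth", 6),
            learning_rate=hp.get("learning_rate", 0.1), scale_pos_weight=spw,
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0)
    if family == "decision_tree":
        return DecisionTreeClassifier(
            max_depth=hp.get("max_depth"), min_samples_leaf=hp.get("min_samples_leaf", 1),
            class_weight=cw, random_state=seed)
    raise ValueError(f"unknown model_family {family!r}")


def _check_observed(table: FeatureTable, stage: str) -> None:
    if table.mask.any():
        cols = [table.columns[j] for j in np.nonzero(table.mask.any(axis=0))[0]]
        raise ValueError(
            f"{stage}: missing values present in column(s) {cols}; "
            "run the imputation stage first (the pipeline does not impute)")


def fit(config: PipelineConfig, train: FeatureTable) -> TrainedModel:
    """Fit scaler → RFE (logistic scorer, one feature per step) → classifier.

    Records the surviving feature subset. Errors if any cell is masked or if
    only one class is present.
    """
    config.validate()
    _check_observed(train, "fit")
    y = np.asarray(train.labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    steps = [
        ("scaler", _make_scaler(config.scaler)),
        ("rfe", RFE(LogisticRegression(max_iter=2000, random_state=config.seed),
                    n_features_to_select=config.n_features_selected, step=1)),
        ("clf", _make_classifier(config, y)),
    ]
    pipe = Pipeline(steps)
    pipe.fit(train.values, y)
    support = pipe.named_steps["rfe"].support_
    selected = tuple(name for name, keep in zip(train.columns, support) if keep)
    cv_auc = None
    summary = {
        "n": train.n,
        "prevalence": float(y.mean()),
        "cv_mean_auc": cv_auc,
    }
    return TrainedModel(config=config, selected_features=selected,
                        fitted_state=pipe, training_summary=summary)


def predict_scores(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """Class-1 (sepsis) confidence score in [0, 1] per row.

    The table must carry the full training column roster, fully observed;
    masked columns are reported by name.
    """
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks feature column(s) {missing}")
    _check_observed(table, "predict_scores")
    scores = model.fitted_state.predict_proba(table.values)[:, 1]
    return np.clip(scores, 0.0, 1.0)


# --------------------------------------------------------------------------
# Fixed-threshold biomarker baselines
# --------------------------------------------------------------------------

def threshold_baseline(table: FeatureTable, feature: str, threshold: float,
                       direction: str = "greater") -> np.ndarray:
    """Single-biomarker rule: sepsis iff the comparison holds; never abstains.

    ``direction`` is 'greater' (strict) or 'greater_equal'. Masked cells in
    the feature column are an error.
    """
    if direction not in ("greater", "greater_equal"):
        raise ValueError(f"direction must be 'greater' or 'greater_equal', got {direction!r}")
    if table.column_mask(feature).any():
        raise ValueError(f"masked cells in feature {feature!r}")
    x = table.column(feature)
    flag = x > threshold if direction == "greater" else x >= threshold
    out = np.full(table.n, NO_SEPSIS, dtype=object)
    out[flag] = SEPSIS
    return out
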