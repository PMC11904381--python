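"""End-to-end study orchestration: train on one cohort, validate everywhere.

Reproduces the study design as a single seeded computation: a stratified
75/25 split of the training cohort, randomized hyperparameter search per
model family scored by cross-validated AUC, refit on the training portion
for internal validation and on the whole training cohort for external
validation, evaluation of standard, cautious (abstaining), decision-rule
(PDR) and fixed-threshold baseline variants on every cohort, MDW imputation
for cohorts lacking the feature, and the three chi-square hypothesis
families with adaptive step-down FDR adjustment. No cohort pooling: external
cohorts are never visible to tuning or fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _pkg_version
from .cautious import (ABSTAIN, SEPSIS, CautiousConfig, cautious_predict,
                       coverage as _coverage, hc_evaluate, pdr_predict_table)
from .cohorts import CohortSpec, FeatureTable, builtin_cohort_specs, generate_cohort
from .fdr import HypothesisResult, adjust_results, chi_square_compare
from .imputation import fit_imputer, impute_feature
from .metrics import ConfusionCounts, MetricEstimate, confusion, rate_metrics, snb
from .metrics import standard_metrics
from .pipeline import TrainedModel, fit, predict_scores, threshold_baseline, tune_hyperparameters

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "summarize",
    "report_linear_coefficients",
]

RATE_METRICS = ("sensitivity", "specificity", "ppv", "npv")

#: Fixed single-biomarker baselines: (name, feature, threshold, direction).
DEFAULT_BASELINES = (
    ("baseline_mdw", "mdw", 23.5, "greater"),
    ("baseline_crp", "crp", 80.0, "greater"),
)


@dataclass
class StudyConfig:
    """Everything needed to re-run the study bit-identically."""

    train_cohort: str = "PA-ED"
    eval_cohorts: tuple[str, ...] = ("AR-ED", "PA-ICU", "PD-ICU", "UD-ED")
    non_mdw_cohorts: tuple[str, ...] = ("OGSA-ICU",)
    families: tuple[str, ...] = ("logistic_regression", "gradient_boosted_trees")
    budget: int = 50
    folds: int = 5
    th: float = 0.75
    alpha: float = 0.05
    snb_threshold: float = 0.5
    decision_threshold: float = 0.5
    train_fraction: float = 0.75
    seed: int = 0
    baselines: tuple = DEFAULT_BASELINES
    cohorts: dict[str, CohortSpec] | None = None  # None -> built-in specs

    def validate(self) -> None:
        overlap = set(self.eval_cohorts) & {self.train_cohort}
        if overlap:
            raise ValueError(f"train cohort must not appear in eval_cohorts: {overlap}")
        specs = self.resolve_cohorts()
        for cid in (self.train_cohort, *self.eval_cohorts, *self.non_mdw_cohorts):
            if cid not in specs:
                raise ValueError(f"cohort {cid!r} not resolvable")

    def resolve_cohorts(self) -> dict[str, CohortSpec]:
        return self.cohorts if self.cohorts is not None else builtin_cohort_specs(self.seed)


@dataclass
class StudyReport:
    """The model x cohort x metric grid plus FDR-adjusted comparisons."""

    grid: dict  # model -> cohort -> {"standard": {...}, "hc": {...}, "coverage": float|None}
    comparisons: list[HypothesisResult]
    provenance: dict


def _confusion_from_decisions(decisions: np.ndarray, labels: np.ndarray) -> ConfusionCounts | None:
    covered = decisions != ABSTAIN
    if not covered.any():
        return None
    return confusion((decisions[covered] == SEPSIS).astype(int), labels[covered])


def _decision_metrics(decisions, labels, alpha, snb_threshold) -> dict[str, MetricEstimate]:
    """Metric panel for a score-free tri-label rule (rate metrics + sNB)."""
    c = _confusion_from_decisions(np.asarray(decisions, dtype=object), labels)
    names = RATE_METRICS + ("snb",)
    if c is None:
        return {m: MetricEstimate.undefined(m, alpha) for m in names}
    out = rate_metrics(c, alpha)
    out["snb"] = snb(c, snb_threshold, alpha)
    return out


def _score_cell(scores, labels, cfg: StudyConfig) -> dict:
    std = standard_metrics(scores, labels, threshold=cfg.decision_threshold,
                           snb_threshold=cfg.snb_threshold, alpha=cfg.alpha)
    res = hc_evaluate(scores, labels, CautiousConfig(cfg.th),
                      snb_threshold=cfg.snb_threshold, alpha=cfg.alpha)
    return {"standard": std, "hc": res.hc_metrics, "coverage": res.coverage,
            "n": int(len(labels))}


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full study; every stochastic step is seeded from config."""
    config.validate()
    specs = config.resolve_cohorts()
    needed = (config.train_cohort, *config.eval_cohorts, *config.non_mdw_cohorts)
    tables: dict[str, FeatureTable] = {}
    offset = 0
    for cid in needed:
        try:
            tables[cid] = generate_cohort(specs[cid])
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"stage=generate cohort={cid}: {exc}") from exc
        # globally unique row ids so cross-cohort blindness is checkable
        tables[cid].ids = tables[cid].ids + offset
        offset += tables[cid].n

    train_full = tables[config.train_cohort]
    train, internal_test = split_train = _split(train_full, config)

    # External cohorts must be blind to everything fit-related.
    train_ids = set(map(int, train_full.ids))
    del split_train

    # MDW imputation for non-MDW cohorts: imputer pooled over the cohorts
    # where MDW is observed (training + external), never the target cohort.
    imputed: dict[str, FeatureTable] = {}
    if config.non_mdw_cohorts:
        donor_ids = [config.train_cohort, *config.eval_cohorts]
        imputer = fit_imputer([tables[c] for c in donor_ids], seed=config.seed,
                              cohort_ids=tuple(donor_ids))
        for cid in config.non_mdw_cohorts:
            try:
                imputed[cid] = impute_feature(imputer, tables[cid])
            except Exception as exc:
                raise RuntimeError(f"stage=impute cohort={cid}: {exc}") from exc

    eval_tables: dict[str, FeatureTable] = {"internal_test": internal_test}
    for cid in config.eval_cohorts:
        eval_tables[cid] = tables[cid]
    for cid in config.non_mdw_cohorts:
        eval_tables[cid] = imputed[cid]

    grid: dict = {}
    models: dict[str, tuple[TrainedModel, TrainedModel]] = {}
    internal_conf: dict[tuple[str, str], ConfusionCounts] = {}

    for family in config.families:
        try:
            search = tune_hyperparameters(train, family, budget=config.budget,
                                          k=config.folds, seed=config.seed)
            model_internal = fit(search.best_config, train)
            model_external = fit(search.best_config, train_full)
        except Exception as exc:
            raise RuntimeError(f"stage=train family={family}: {exc}") from exc
        models[family] = (model_internal, model_external)
        grid[family] = {}
        for cid, table in eval_tables.items():
            model = model_internal if cid == "internal_test" else model_external
            try:
                scores = predict_scores(model, table)
            except Exception as exc:
                raise RuntimeError(f"stage=predict family={family} cohort={cid}: {exc}") from exc
            grid[family][cid] = _score_cell(scores, table.labels, config)
            grid[family][cid]["scores"] = scores

    # PDR rule model and fixed-threshold baselines (score-free).
    rule_models = {"pdr": lambda t: pdr_predict_table(t)}
    for name, feature, thr, direction in config.baselines:
        rule_models[name] = (
            lambda t, f=feature, th=thr, d=direction: threshold_baseline(t, f, th, d))
    for mname, predictor in rule_models.items():
        grid[mname] = {}
        for cid, table in eval_tables.items():
            try:
                decisions = predictor(table)
            except Exception as exc:
                raise RuntimeError(f"stage=rule model={mname} cohort={cid}: {exc}") from exc
            cell = {
                "standard": _decision_metrics(decisions, table.labels,
                                              config.alpha, config.snb_threshold),
                "hc": None,
                "coverage": _coverage(decisions),
                "n": int(table.n),
            }
            grid[mname][cid] = cell

    # --- Hypothesis families -------------------------------------------------
    comparisons: list[HypothesisResult] = []

    def _std_confusion(family: str, cid: str) -> ConfusionCounts:
        key = (family, cid)
        if key not in internal_conf:
            scores = grid[family][cid]["scores"]
            y = eval_tables[cid].labels
            internal_conf[key] = confusion(
                (scores >= config.decision_threshold).astype(int), y)
        return internal_conf[key]

    fam1: list[HypothesisResult] = []
    for i, f1 in enumerate(config.families):
        for f2 in config.families[i + 1:]:
            for metric in RATE_METRICS:
                fam1.append(chi_square_compare(
                    _std_confusion(f1, "internal_test"),
                    _std_confusion(f2, "internal_test"),
                    metric, tails="two",
                    hypothesis_id=f"{f1}-vs-{f2}:{metric}",
                    family="model_vs_model_2tailed"))

    fam2: list[HypothesisResult] = []
    for family in config.families:
        for cid in eval_tables:
            scores = grid[family][cid]["scores"]
            y = eval_tables[cid].labels
            hc_c = _confusion_from_decisions(
                cautious_predict(scores, CautiousConfig(config.th)), y)
            if hc_c is None:
                continue
            for metric in RATE_METRICS:
                fam2.append(chi_square_compare(
                    hc_c, _std_confusion(family, cid), metric, tails="one",
                    hypothesis_id=f"{family}@{cid}:hc-improves-{metric}",
                    family="cautious_improvement_1tailed"))

    fam3: list[HypothesisResult] = []
    for family in config.families:
        for cid in (*config.eval_cohorts, *config.non_mdw_cohorts):
            for metric in RATE_METRICS:
                fam3.append(chi_square_compare(
                    _std_confusion(family, "internal_test"),
                    _std_confusion(family, cid), metric, tails="two",
                    hypothesis_id=f"{family}:internal-vs-{cid}:{metric}",
                    family="internal_vs_external_2tailed"))

    for fam in (fam1, fam2, fam3):
        comparisons.extend(adjust_results(fam, config.alpha))

    # scores are working state, not part of the report contract
    for mname in grid:
        for cid in grid[mname]:
            grid[mname][cid].pop("scores", None)

    provenance = {
        "package_version": _pkg_version,
        "config": {
            "train_cohort": config.train_cohort,
            "eval_cohorts": list(config.eval_cohorts),
            "non_mdw_cohorts": list(config.non_mdw_cohorts),
            "families": list(config.families),
            "budget": config.budget,
            "folds": config.folds,
            "th": config.th,
            "alpha": config.alpha,
            "snb_threshold": config.snb_threshold,
            "decision_threshold": config.decision_threshold,
            "train_fraction": config.train_fraction,
            "seed": config.seed,
            "baselines": [list(b) for b in config.baselines],
        },
        "cohort_sizes": {cid: int(tables[cid].n) for cid in tables},
        "selected_features": {
            family: list(models[family][1].selected_features) for family in models
        },
        "train_row_ids_disjoint_from_external": all(
            train_ids.isdisjoint(set(map(int, tables[c].ids))) or c == config.train_cohort
            for c in needed),
    }
    return StudyReport(grid=grid, comparisons=comparisons, provenance=provenance)


def _split(train_full: FeatureTable, config: StudyConfig):
    from .pipeline import split_train_test
    try:
        return split_train_test(train_full, config.train_fraction, config.seed)
    except Exception as exc:
        raise RuntimeError(f"stage=split cohort={config.train_cohort}: {exc}") from exc


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _metric_to_json(m: MetricEstimate | None):
    return None if m is None else m.as_dict()


def _cell_to_json(cell: dict) -> dict:
    return {
        "standard": {k: _metric_to_json(v) for k, v in cell["standard"].items()},
        "hc": (None if cell["hc"] is None
               else {k: _metric_to_json(v) for k, v in cell["hc"].items()}),
        "coverage": cell["coverage"],
        "n": cell["n"],
    }


def report_to_json(report: StudyReport) -> dict:
    return {
        "grid": {m: {c: _cell_to_json(cell) for c, cell in row.items()}
                 for m, row in report.grid.items()},
        "comparisons": [
            {
                "hypothesis_id": r.hypothesis_id,
                "family": r.family,
                "statistic": None if not r.defined else r.statistic,
                "p_raw": None if not r.defined else r.p_raw,
                "p_adjusted": r.p_adjusted,
                "rejected_at_alpha": r.rejected_at_alpha,
                "defined": r.defined,
            }
            for r in report.comparisons
        ],
        "provenance": report.provenance,
    }


def _fmt(m: MetricEstimate | None) -> str:
    if m is None or not m.defined:
        return "—"
    return f"{m.value:.2f} ({m.ci_low:.2f}, {m.ci_high:.2f})"


def summarize(report: StudyReport, format: str = "table") -> str:
    """Deterministic rendering of a StudyReport.

    ``format='json'`` is a lossless serialization; ``format='table'`` renders
    one metric grid per cohort with undefined cells printed as em-dashes and
    CIs in parentheses.
    """
    if format == "json":
        return json.dumps(report_to_json(report), indent=2, sort_keys=True)
    if format != "table":
        raise ValueError(f"unknown format {format!r}")
    models = list(report.grid)
    cohorts = list(next(iter(report.grid.values())))
    metric_rows = ("sensitivity", "specificity", "ppv", "npv", "auc", "a_ppv",
                   "brier", "snb")
    lines = []
    for cid in cohorts:
        lines.append(f"== {cid} ==")
        header = ["metric"] + models
        lines.append("\t".join(header))
        for metric in metric_rows:
            row = [metric]
            for m in models:
                row.append(_fmt(report.grid[m][cid]["standard"].get(metric)))
            lines.append("\t".join(row))
        for metric in ("sensitivity", "specificity", "ppv", "npv"):
            row = [f"hc_{metric}"]
            for m in models:
                hc = report.grid[m][cid]["hc"]
                row.append(_fmt(hc.get(metric)) if hc else "—")
            lines.append("\t".join(row))
        cov_row = ["coverage"]
        for m in models:
            cov = report.grid[m][cid]["coverage"]
            cov_row.append("—" if cov is None else f"{cov:.2f}")
        lines.append("\t".join(cov_row))
        lines.append("")
    if report.comparisons:
        lines.append("== comparisons (FDR-adjusted) ==")
        for r in report.comparisons:
            if not r.defined:
                lines.append(f"{r.hypothesis_id}\t—")
                continue
            lines.append(
                f"{r.hypothesis_id}\tchi2={r.statistic:.3f}\tp={r.p_raw:.4g}"
                f"\tp_adj={r.p_adjusted:.4g}\t{'*' if r.rejected_at_alpha else ''}")
        lines.append("")
    return "\n".join(lines)


def report_linear_coefficients(model: TrainedModel) -> dict[str, float]:
    """Coefficients of a fitted logistic-regression pipeline.

    Reported on the scaled feature space, keyed by selected feature name and
    sorted by decreasing magnitude. Errors for non-linear families.
    """
    if model.config.model_family != "logistic_regression":
        raise ValueError(
            f"linear coefficients are only defined for logistic_regression, "
            f"got {model.config.model_family!r}")
    clf = model.fitted_state.named_steps["clf"]
    coefs = np.asarray(clf.coef_).ravel()
    if len(coefs) != len(model.selected_features):
        raise RuntimeError("coefficient/feature length mismatch")
    pairs = sorted(zip(model.selected_features, coefs),
                   key=lambda kv: -abs(kv[1]))
    return {name: float(c) for name, c in pairs}
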