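# sepsiscreen

Cautious machine-learning screening of sepsis from complete blood count
(CBC) parameters and the monocyte distribution width (MDW), with the full
external-validation and statistical apparatus needed to study how such
screeners behave under distribution shift.

## The problem

Early sepsis recognition in the emergency department is hard: the Sepsis-3
work-up (SOFA scoring plus infection assessment) needs data that are rarely
available at presentation, while single biomarkers that *are* available —
MDW, C-reactive protein (CRP) — have excellent negative predictive value but
poor sensitivity and positive predictive value (PPV). Combining the CBC
panel (19 features: age, sex, leucocyte differential, MDW, CRP, red-cell
indices, platelets and the neutrophils-to-lymphocytes ratio NLR) through
supervised learning can do better, but models trained in one hospital
routinely degrade in another because of covariate shift (ED vs ICU
populations), label shift (Sepsis-2 vs Sepsis-3 diagnostic criteria) and
missingness shift (analyzers that do not report MDW at all).

`sepsiscreen` implements that study design end to end:

- **Synthetic cohorts** (`sepsiscreen.cohorts`) — six parametric cohorts
  matching published per-cohort feature means/SDs, sex ratios, sepsis
  prevalences (4.59%–33.5%) and sample sizes, with controllable
  class-conditional effect sizes, borderline label flips and per-feature
  missingness; the MDW-less ICU cohort has MDW 100% masked.
- **Tuned pipelines** (`sepsiscreen.pipeline`) — 3-step scikit-learn
  pipelines (scaling → recursive feature elimination under a logistic
  scorer → classifier) for logistic regression, calibrated linear SVM,
  random forest, XGBoost and decision trees; randomized hyperparameter
  search scored by mean AUC over stratified k-fold cross-validation;
  fixed-threshold MDW/CRP baselines.
- **Cautious layer** (`sepsiscreen.cautious`) — abstention when the sepsis
  confidence `s` falls in `(1−th, th)` (default `th = 0.75`): commit to
  sepsis when `s ≥ th`, to no-sepsis when `s ≤ 1−th`; coverage and
  high-confidence (HC) metrics on the committed subset; plus the printed
  two-feature partial decision rule (PDR) over MDW and neutrophils.
- **Metrics & CIs** (`sepsiscreen.metrics`) — sensitivity, specificity,
  PPV, NPV (Wald CIs), Mann–Whitney AUC and average PPV with exact tie
  handling (Wald-form CIs on a Hanley–McNeil SE), Brier score (Hoeffding
  CI), standardized net benefit `sNB = [sens·π − (1−spec)(1−π)·t/(1−t)]/π`.
- **Hypothesis tests & FDR** (`sepsiscreen.fdr`) — Pearson chi-square model
  comparisons on rate metrics and the Gavrilov–Benjamini–Sarkar adaptive
  step-down FDR procedure with critical constants
  `c_k = kα/(m+1−k(1−α))`.
- **MDW imputation** (`sepsiscreen.imputation`) — a pooled random-forest
  regressor predicting MDW from the other 18 features, evaluated by
  adjusted R² on a 75/25 hold-out, then applied to cohorts lacking MDW.
- **Study harness** (`sepsiscreen.study`) — the whole design in one seeded
  call: 75/25 stratified split, per-family tuning, internal and external
  validation of standard/cautious/PDR/baseline variants, imputation for
  non-MDW cohorts, three chi-square hypothesis families, FDR adjustment.

## Worked example

```python
import sepsiscreen as ss

specs = ss.builtin_cohort_specs(seed=0)
cohort = ss.generate_cohort(specs["PA-ED"])            # n=1809, prevalence 4.59%
train, test = ss.split_train_test(cohort, fraction=0.75, seed=0)

search = ss.tune_hyperparameters(train, "logistic_regression",
                                 budget=10, k=5, seed=0)
model = ss.fit(search.best_config, train)
scores = ss.predict_scores(model, test)

panel = ss.standard_metrics(scores, test.labels)
for name in ("sensitivity", "specificity", "ppv", "npv", "auc", "brier", "snb"):
    m = panel[name]
    print(f"{name:12s} {m.value:.3f} (95% CI {m.ci_low:.3f}-{m.ci_high:.3f}, {m.ci_method})")

res = ss.hc_evaluate(scores, test.labels, ss.CautiousConfig(th=0.75))
print(f"coverage     {res.coverage:.3f}")
print(f"hc_ppv       {res.hc_metrics['ppv'].value:.3f}")

decisions = ss.pdr_predict_table(test)
print(f"pdr_coverage {ss.coverage(decisions):.3f}")
```

prints

```
sensitivity  0.545 (95% CI 0.337-0.754, wald)
specificity  0.993 (95% CI 0.985-1.000, wald)
ppv          0.800 (95% CI 0.598-1.000, wald)
npv          0.977 (95% CI 0.963-0.991, wald)
auc          0.985 (95% CI 0.949-1.000, riley_se)
brier        0.020 (95% CI 0.000-0.084, hoeffding)
snb          0.409 (95% CI 0.295-0.523, riley_se)
coverage     0.976
hc_ppv       1.000
pdr_coverage 0.892
```

Read: at the default 0.5 decision threshold the tuned logistic model ranks
almost perfectly (AUC 0.985) but, at this 4.6% prevalence, catches only
55% of sepsis cases while keeping PPV at 0.80; the cautious layer commits
on 97.6% of the internal test cases and its committed positive calls are
all correct (HC PPV 1.0); the interpretable MDW/neutrophils rule abstains
on ~11% of cases. CI methods are named per metric (Wald for rates,
Hanley–McNeil standard error for rank metrics, Hoeffding for Brier).

A command-line layer mirrors the library (`sepsiscreen generate`,
`evaluate`, `cautious-eval`, `pdr`, `fdr-adjust`, `impute`, `run-study`,
`summarize`); see `sepsiscreen --help`.

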