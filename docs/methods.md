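# Methods

This note documents the models and procedures implemented in `sepsiscreen`,
the defaults and their rationale, what the synthetic cohorts do and do not
emulate, and the numerical choices a user should know before trusting or
extending the results.

## Synthetic cohort model

No patient-level data accompany the study design this package implements;
the generator therefore produces parametric stand-ins constrained to the
published cohort summaries: per-feature mean and SD, sex ratio, sepsis
prevalence and sample size for six cohorts (three emergency-department,
three intensive-care) spanning prevalences from 4.59% to 33.5%.

**Class-conditional structure.** Published summaries are pooled over
classes, so the class-conditional distributions are a modeling choice:
non-sepsis rows are drawn at the reference (mean, SD) and sepsis rows with
the mean displaced by a standardized effect size. Defaults — MDW +2.0 SD,
CRP +1.5, neutrophils +1.0, lymphocytes −0.5, all others 0 — make MDW the
dominant predictor, matching the feature-importance finding that MDW is the
single most informative feature in this panel, followed by CRP and the
leucocyte counts. These effect sizes are tunable stand-ins, not estimates
of the real cohorts.

**Truncation.** Continuous features are drawn from a normal truncated below
at a physical floor (0 for counts and concentrations; 18 for age, the adult
inclusion bound; 0.1 for lymphocytes so the derived NLR stays finite). A
consequence worth knowing: for features whose printed SD exceeds the mean
(CRP, some lymphocyte entries) a lower-truncated normal cannot reproduce
the printed mean — its coefficient of variation is bounded by 1 — so the
realized mean of such features sits above the printed location parameter.
These features are strongly right-skewed in real patients; the truncated
normal is a deliberate simplification, and tests of mean recovery are
restricted to features whose floor is non-binding (more than ~2.5 SD below
the mean).

**Derived feature.** NLR is always recomputed as neutrophils/lymphocytes,
never drawn, so the functional dependence holds exactly (relative tolerance
1e-9) on every generated table.

**Label-criterion shift.** Alternative diagnostic criteria (Sepsis-2 vs
Sepsis-3) relabel borderline patients, not random ones. The generator
therefore flips the labels of the `label_noise` fraction of rows *nearest
the class boundary in MDW* (the midpoint between the two class means).
Cohorts whose real-world counterparts used Sepsis-3 get a default 2% flip
fraction; the training cohort gets 0.

**Missingness.** Per-feature Bernoulli masks at configurable rates; the
MDW-less ICU cohort has MDW masked at rate 1.0 (its analyzer does not
report the parameter). Masked cells hold NaN and a True mask bit; NaN never
appears elsewhere. For that cohort the latent MDW distribution (needed to
draw before masking) is the training cohort's reference — it is never
observable, so the choice is inert. The printed MCHC anomaly for that
cohort (66.1 ± 327.5) is reproduced as printed, without interpretation.

**Seeding.** One master seed per cohort; each feature, the labels, the flip
selection and each missingness mask use deterministic sub-streams
(`SeedSequence([seed, stream_index])`), so adding a feature never perturbs
the draws of the others, and identical specs yield bit-identical tables.

**What the generator does not emulate.** Between-feature correlations
(beyond NLR's functional dependence) are absent because the published
summaries carry no covariance information; real CBC features are strongly
correlated (WBC with the differential, hemoglobin with hematocrit).
Passing tests on these cohorts therefore demonstrate the *machinery* —
selection, calibration, abstention, shift response — not clinical
performance; no number produced here estimates real-cohort accuracy.

## Classification pipelines

Each model is a 3-step pipeline: scaler (standard, min-max, robust or
none) → recursive feature elimination → classifier. RFE scores features by
the absolute coefficients of a logistic model on the scaled space and drops
one feature per iteration until `n_features_selected` remain (step size is
a free choice; one-at-a-time is the most conservative). Margin classifiers
(linear SVM) are wrapped in sigmoid calibration fitted in-fold so every
family emits confidences in [0, 1], which the cautious layer requires.
Missing values are a hard error at fit and predict time — imputation is an
explicit, separate stage, mirroring a flow where only the non-MDW system
imputes.

**Search.** Randomized search samples uniformly from per-family grids:
regularization strength 1e-4…1e4 (log grid) for logistic/SVM; tree depth
2–12; estimator counts {50, 100, 200, 400}; learning rate {0.01, 0.05,
0.1, 0.3}; shared dimensions scaler, `n_features_selected ∈ {5, 8, 10, 12,
15, 19}` and class weighting {none, balanced}. Configurations are scored
by mean AUC over stratified k-fold cross-validation (default k=5); the
first trial attaining the maximum wins, making the search deterministic
given its seed. The grids reproduce the search *procedure*; the original
study's exact grid was not published in the available text.

**Baselines.** Fixed single-biomarker thresholds, strict by default:
MDW > 23.5 and CRP > 80. A "Sepsis Index" baseline is supported only as a
precomputed input column, since its definition is external.

## Cautious classification

Thresholding on the confidence score: sepsis at `s ≥ th`, no-sepsis at
`s ≤ 1−th`, abstain strictly inside `(1−th, th)`; default `th = 0.75`. The
boundary is committed (≥, ≤), following the more detailed of the two
published phrasings; the open-interval abstention region makes the three
decisions a partition. Coverage is the exact fraction of committed rows.
HC (high-confidence) metrics are the standard panel restricted to the
committed rows; rank metrics (AUC, A-PPV, Brier) use the committed rows'
raw scores rather than re-thresholded decisions. Any metric whose
denominator is empty on the committed subset is reported as explicitly
undefined — never silently zero — and renderers print an em-dash.

The PDR rule model (MDW > 24.1 → sepsis; MDW ≤ 24.1 ∧ neutrophils ≤ 8.6 →
no sepsis; MDW ≤ 20.5 ∧ neutrophils > 8.6 → no sepsis; else abstain) is
taken literally from its printed inequalities, including strictness at the
cut-points; its abstention region is exactly 20.5 < MDW ≤ 24.1 with
neutrophils > 8.6.

## Metrics and confidence intervals

- **Rates** (sensitivity, specificity, PPV, NPV): Wald intervals
  `p ± z_{α/2}·√(p(1−p)/n)` on the metric's own denominator, clipped to
  [0, 1]. These degenerate to zero width at p ∈ {0, 1}, a known property
  of the Wald form.
- **AUC**: Mann–Whitney statistic (midranks; ties count ½). CI is
  Wald-form around the estimate with the Hanley–McNeil standard error
  `SE² = [v(1−v) + (n⁺−1)(Q₁−v²) + (n⁻−1)(Q₂−v²)]/(n⁺n⁻)`,
  `Q₁ = v/(2−v)`, `Q₂ = 2v²/(1+v)` — a documented stand-in for the
  sample-size formulas the original analysis cites; the method is recorded
  in every `MetricEstimate` so it can be swapped.
- **A-PPV** (average PPV, i.e. average precision): mean over positives of
  the precision at each positive's rank under descending score. Ties are
  resolved *exactly in expectation* over all orderings of each tied block,
  via the hypergeometric distribution of the k-th positive's position
  within the block. Note this differs from the common grouped-step
  shortcut: for a single tied positive–negative pair the expectation is
  0.75, the grouped step gives 0.5. The exact expectation is deterministic
  and matches a brute-force permutation average, which is what the tests
  assert.
- **Brier**: mean squared error between score and outcome; CI from the
  Hoeffding inequality, half-width `√(ln(2/α)/(2n))` — distribution-free
  and conservative (empirical coverage ≈ 1 at nominal 95%).
- **sNB**: net benefit at threshold t, standardized by prevalence:
  `sNB = [sens·π − (1−spec)(1−π)·t/(1−t)]/π`, evaluated at the fixed
  t = 0.5. This is the standard decision-curve construction; sNB can be
  negative (a harmful operating point at low prevalence), so only the
  upper CI end is clipped (at 1), and the Hanley–McNeil SE is evaluated at
  the estimate clipped into [0, 1].

## Hypothesis testing and FDR

Model comparisons on rate metrics use the Pearson chi-square statistic
(no continuity correction) on the 2×2 success/failure table over the
metric's denominator — e.g. sensitivity compares {TP, FN} between models
over positives. Rank metrics (AUC, A-PPV, Brier, sNB) have no natural 2×2
success/failure decomposition, so chi-square comparisons are restricted to
the four rates. Directional (one-tailed) tests halve the two-tailed p when
the observed difference matches the hypothesized direction and report
`1 − p/2` otherwise, since the chi-square statistic itself is unsigned.

Multiplicity: the Gavrilov–Benjamini–Sarkar optimal adaptive step-down
procedure, `c_k = kα/(m+1−k(1−α))`, rejecting the largest sorted prefix
with `p_(i) ≤ c_i` throughout. Adjusted p-values are the smallest α at
which each sorted p would be rejected — `p(m+1−k)/(k(1−p))`, running-max
enforced — so "adjusted ≤ α" reproduces the step-down decision exactly; at
m = 1 the rule reduces to `p ≤ α/(1+α)`. The three hypothesis groups
(model-vs-model two-tailed; cautious-improvement one-tailed;
internal-vs-external two-tailed) are adjusted as separate families by
default; pooling them is a one-line change at the call site.

## MDW imputation

A random-forest regressor (100 trees, unlimited depth, all features
considered at every split — the library's regression default — fixed seed)
predicts MDW from the other 18 features, trained on rows pooled across all
MDW-bearing cohorts with no reweighting. Goodness of fit is the adjusted
R² `1 − (1−R²)(n−1)/(n−p−1)` on a held-out 25% of the pooled rows, with
fit/evaluation rows disjoint by construction. The assessed model is refit
on all pooled rows and applied to fill only the masked MDW cells of a
target cohort; observed cells are untouched and re-imputation is a no-op.
Predictions are floored at 0. On the default synthetic cohorts, where MDW
is conditionally independent of the other features given the label, the
achievable R² is intrinsically modest; recovery tests therefore plant an
explicit functional relation.

## Study harness

`run_study` executes the design with a single seed: 75/25 stratified split
of the training cohort (internal models are fit on the 75% portion;
external-validation models are refit with the winning configuration on the
whole training cohort), per-family tuning, evaluation of every variant on
the internal test split and each external cohort, imputation before
scoring cohorts lacking MDW, and the three FDR-adjusted hypothesis
families. External cohorts are never pooled into training, and row ids are
globally unique so the blindness invariant is checkable (recorded in the
report provenance). Reports carry per-cell n and defined-flags, and the
JSON rendering is deterministic and lossless.

## Problem sizes and defaults

The acceptance script runs the built-in cohorts at their published sizes
(1809/308/75/2114/938/100) with a search budget of 12 configurations per
family over 5 folds — the search procedure and evaluation grid, not an
exhaustive search, are the object under study; the budget is a package
default chosen to keep a complete seeded rerun inexpensive on one CPU.
Simulation-based checks (CI coverage, FDR control) use 2000 replicates;
shift and coefficient-null properties use 10–20 seeded replicates and
compare medians.

## Known limitations

- Independent features (no copulas/covariance): synthetic difficulty is
  optimistic relative to correlated real data.
- Truncated-normal marginals cannot reproduce printed moments for
  heavily skewed features (see above).
- The Hanley–McNeil SE is a stand-in for the originally cited CI
  construction for AUC/A-PPV/sNB, and the sNB definition here is the
  standard decision-curve one; published sNB values computed otherwise are
  not comparable.
- Chi-square comparisons are unpaired; paired alternatives (McNemar) would
  be more powerful when both models score the same rows.
- No longitudinal structure, unit conversion, or uncertainty propagation
  from imputation into downstream scores.
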