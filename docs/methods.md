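# Methods

## Scope and design

The package reconstructs, as a tested pipeline, a severity-graded analysis
of stroke recurrence after mechanical thrombectomy for MCA occlusion: rule-
based severity grading, an importance-fusion recurrence score, and two- and
three-way interaction analyses between that score and clinical risk
factors. The source cohort (n = 272) is not deposited, so all empirical
work here runs on synthetic cohorts; every quantitative claim in this
repository is one the test suite or `scripts/acceptance.py` computes at run
time.

## Synthetic cohorts

### What the generator emulates

Covariate marginals are calibrated to the published baseline tables of the
272-patient cohort: prevalences for binary variables (e.g. smoking 29.04%),
category proportions for ordinal ones (e.g. infarct size 11.4 / 54.8 /
33.8%), and median plus observed range for continuous ones (e.g. WBC 12.3,
range 8.4–16.6 ×10⁹/L).

Continuous draws use truncated distributions on the observed range with the
location solved (Brent root-finding on the truncated quantile function) so
the *truncated* median equals the published median; the scale is fixed at
range/4. Biomarkers use this scheme in log space (truncated log-normal) to
respect positive support and right skew; age, NIHSS, treatment window and
thrombectomy duration use a truncated normal, with integer-valued variables
rounded. With these choices the generator reproduces each published
prevalence and median to well under 1–2% at n = 50,000 (tested).

Two recurrence-time grading inputs are not tabulated in the source and are
the package's own choice, made once: infarct volume ~ truncated log-normal,
median 0.8 cm³ on (0.05, 8), and recurrence NIHSS ~ truncated normal,
median 4 on (0, 24). They populate all three severity bands under the max
rule (roughly 35 / 53 / 12% in the worked example) and play no role in any
model fit.

### What it does not emulate

Covariates are drawn independently; the source reports no correlation
structure, and the published VIF screen (~1.0 throughout) is consistent
with near-independence, but real biomarker panels are correlated. The
90-day recurrence window is treated purely as label semantics — no
time-to-event structure, no missing data (the source excluded incomplete
records). Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under known generating models, not that the score
would transport to a real cohort.

### Outcome models

Outcomes are Bernoulli draws from a logistic model with explicit main,
pairwise-product and triple-product log-odds terms; continuous covariates
enter z-standardized (per-SD effects). Two named defaults:

- `biomarker_signal_model()` — log-odds 0.8/SD on LDH, WBC, NIHSS and IL-6
  only (OR ≈ 2.2/SD, a moderate clinical effect), intercept 0.15 keeping
  event prevalence near the source's 54%. Used for feature-recovery
  experiments: the question is whether the pipeline finds exactly these
  four.
- `default_outcome_model()` — the same biomarkers at 0.6/SD plus age
  (0.3/SD), smoking (0.5) and infarct size (0.4/step) with one known
  pairwise (smoking×size, 0.3) and one triple (age×smoking×size, 0.2)
  term, for the narrative analyses.

A single user seed expands into fixed per-stage child seeds via
`numpy.random.SeedSequence` spawn keys, so stages are independently
reproducible; identical (spec, model, seed) yields bit-identical cohorts.

## Severity grading

Volume bands [0, 1), [1, 3], (3, ∞) cm³ were adopted so the stated
"less than 1 / between 1 and 3 / greater than 3" partition is exhaustive
and disjoint; a volume of exactly 3 cm³ is moderate (the boundary is not
specified in the source rules — this is the package's documented choice).
Diameter is accepted as a fallback when volume is absent, with the same
cut-points; only one imaging quantity ever drives the grade. The
imaging/clinical mismatch rule is a plain max, and the binary outcome is
grade ≥ moderate.

## Importance fusion

- Split: stratified 7:3 with |train| = round(0.7·n) (Python banker's
  rounding; 272 → 190/82).
- Tuning: explicit grid enumeration with 10-fold stratified CV maximizing
  mean AUC; grids are ordered by ascending complexity and ties keep the
  earliest point, so selection is deterministic. Default grids are small
  (4 points per family) — appropriate for n ≈ 190 training sets and cheap
  enough for repeated seeded runs.
- SHAP comes from the boosted model via XGBoost's native TreeSHAP
  (`pred_contribs`), summarized as mean |attribution| over the training
  split by default (a config switch allows the test split; the source does
  not say which was used). Local accuracy (attributions + base = margin) is
  asserted in tests. GINI comes from the forest's impurity importances.
- "Standardized SHAP value and GINI index" is interpreted as z-scores
  across the feature set within each importance type — the two importance
  types have incomparable units, and z-scoring puts them on one scale
  before summing. If all features tie, the z-scores (and hence all
  coefficients) are 0 rather than an error; this matches the degenerate
  limit of the definition.
- The common-top-5 intersection may contain fewer than 5 features (the
  source itself proceeds with 4); an empty intersection warns and returns
  an empty list.
- Score inputs: continuous features z-standardized on the full cohort
  (preventing unit dominance), ordinal/binary as integer codes. The median
  dichotomization is strict (ties at the median code 0).

## Interaction analysis

Joint ORs come from a logistic model with three exposure-cell dummies
against the doubly-unexposed reference (optionally adjusted; unadjusted is
the default). RERI, AP and S follow the canonical additive-interaction
definitions; delta-method gradients with respect to the three dummy
log-ORs are

    RERI: (−OR10, −OR01, OR11)
    AP:   (−OR10/OR11, −OR01/OR11, (OR10+OR01−1)/OR11)
    ln S: (−OR10/D, −OR01/D, OR11/(OR11−1)),  D = OR10+OR01−2.

S's interval is built on ln S when S > 0; when S ≤ 0 (outside the index's
usual domain, which the package flags) a direct untransformed delta
interval is used. S is reported as undefined (NaN) when D = 0, and an
undefined S can never trigger a verdict.

The decision rule is per-indicator triggering — any one of RERI/AP/S
departing from its null with a 95% CI excluding that null suffices — with
a conflict safeguard (indicators pointing both ways yield "none" plus a
diagnostic). This resolves an internal tension in the source's wording
("RERI and AP … and S" versus "one of these three indicators") in favor of
its actual usage, which calls an interaction on a single indicator.

Note that the interaction tables printed in the source are not internally
reconcilable: applying the canonical formulas to its printed OR triples
yields different RERI/AP/S than it prints (e.g. ORs 0.876/0.890/0.973 give
RERI = 0.207, not −0.031), and a negative S alongside a negative numerator
and denominator is arithmetically inconsistent. The package implements the
canonical definitions, validates the delta intervals against bootstrap
resampling and against coverage simulations, and does not attempt to
reverse-engineer the printed values.

The three-way model is the full factorial (3 mains, 3 pairwise products,
1 triple product) fitted by maximum likelihood; empty joint cells (for
binary factors) and rank-deficient designs raise errors naming the problem
rather than returning unstable estimates. Bootstrap CIs resample patients
and refit, tolerating up to 10% degenerate resamples.

## Evaluation

AUC is computed with DeLong's midrank estimator (equal to the Mann–Whitney
normalization; verified against a brute-force pairwise oracle to 1e-12),
with DeLong-variance Wald CIs; with a single positive or negative case the
variance is inestimable and reported NaN. The Youden-optimal threshold is
chosen over observed cut points, taking the lowest threshold on ties.
Predicted labels use prob ≥ threshold with the 0.5 default. Metrics with
empty denominators are NaN, never 0. F1 and accuracy are reported ×100,
mirroring the layout of the report this package reproduces; everything
else is on [0, 1]. Bootstrap metric CIs redraw resamples missing a class
(counted; > 20% aborts).

## Problem sizes

Simulation studies use sizes chosen to make the statistical checks sharp
at interactive cost: 500 replicates of n = 5,000 for RERI null coverage,
1,000 (tests) / 500 (acceptance script) replicates of n = 5,000 for the
three-way type-I error, 200 / 100 replicates of n = 20,000 for triple-term
CI coverage, and 10 seeded n = 272 cohorts for the fusion pipeline — the
published cohort's own size, so recovery rates reflect realistic power.

## Known limitations

- Independence between covariates is a simplification; injected-signal
  recovery rates would degrade under strong biomarker correlation.
- The delta and bootstrap intervals are asymptotic/percentile devices; at
  n = 272 with rare joint cells the three-way model can quasi-separate,
  which the package raises as an error rather than papering over.
- The score's coefficients are importance fusions, not calibrated
  log-odds; the score ranks patients but its scale is arbitrary (tests
  assert scale equivariance of the median coding).
- No calibration assessment (Brier, Hosmer–Lemeshow), survival modeling,
  or additional classifier families.
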