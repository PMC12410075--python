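# strokerecur

Severity-graded stroke-recurrence analysis for middle-cerebral-artery (MCA)
occlusion cohorts treated with mechanical thrombectomy. The package is aimed
at clinical biostatisticians who want to (1) grade recurrent strokes into
mild / moderate / severe from imaging and NIHSS, (2) build a composite
recurrence-severity score by fusing tree-ensemble feature importances, and
(3) quantify how that score interacts — additively and multiplicatively —
with clinical risk factors such as age, smoking history and infarct size.

Hospital cohorts of this kind are rarely shareable, so the package ships a
calibrated synthetic-cohort generator (marginals matched to a published
272-patient MCA-occlusion cohort, outcome from a configurable logistic model
with known interaction structure), making every stage testable end to end
against known ground truth.

## The methods in brief

**Severity grading.** A recurrent infarct is graded on two axes — imaging
(volume < 1 cm³ mild, 1–3 cm³ moderate, > 3 cm³ severe) and clinical (NIHSS
0–5 / 6–15 / ≥ 16) — and on mismatch the worse grade wins. Analyses use the
binary coding moderate+severe = 1, mild = 0.

**Importance-fusion score.** On a stratified 7:3 split, a gradient-boosted
classifier (XGBoost) and a random forest are tuned by 10-fold CV grid
search. Feature importance is summarized as mean |TreeSHAP attribution| from
the boosted model and GINI (mean impurity decrease) from the forest; the
features in both models' top 5 form the score

    score_i = Σ_f  x_if · coef_f ,   coef_f = z(SHAP_f) + z(GINI_f),

with z-scores taken across the feature set within each importance type, and
the score dichotomized strictly above its cohort median.

**Additive interaction.** For two binary exposures with joint odds ratios
OR10, OR01, OR11 (versus both-unexposed), the package computes

    RERI = OR11 − OR10 − OR01 + 1
    AP   = RERI / OR11
    S    = (OR11 − 1) / ((OR10 − 1) + (OR01 − 1))

with delta-method 95% CIs (S on the log scale when S > 0) or patient-level
bootstrap. An index "triggers" synergy when it exceeds its null (0, 0, 1
respectively) with a CI excluding the null, antagonism in the mirror case;
any one triggering index decides the verdict. Multi-level exposures (e.g.
small/moderate/large infarct) are handled as all level-pair contrasts.

**Multiplicative interaction.** Full-factorial logistic models up to the
three-way product term, whose Wald test is the headline synergy call, plus a
multivariable main-effects model and a VIF collinearity pre-check.

**Evaluation.** Confusion-matrix metrics at the 0.5 threshold, AUC with
DeLong variance, Youden-optimal thresholds, bootstrap metric CIs, and the
paired DeLong test (used here to compare the fused score against raw NIHSS).

## Worked example

The numbered scripts under `analysis/` run the full narrative on a
simulated 272-patient cohort (`python analysis/01_simulate_cohort.py`, then
02–05 in order). Representative output:

```
$ python analysis/02_grade_severity.py
severity distribution (grading applied to imaging volume + NIHSS):
      mild: 95 (34.9%)
  moderate: 144 (52.9%)
    severe: 33 (12.1%)

$ python analysis/03_fit_recurrence_score.py
common top-5 features: ['il6', 'ldh', 'wbc']
gradient_boosted_trees: test AUC 0.791 (0.692-0.889), Youden 0.458
random_forest: test AUC 0.795 (0.691-0.898), Youden 0.465
DeLong score vs NIHSS (test): AUC 0.756 vs 0.652, Z = 1.217, p = 0.2238

$ python analysis/04_two_way_interactions.py
score x age_group: RERI 5.685 (-3.691, 15.061), AP 0.474, S 2.071
  -> synergy (triggers: ['AP'])
```

Reading this: the two tuned ensembles agree on three common top-5 features
(all injected signal carriers); the fused score discriminates held-out
recurrence severity about as well as — not significantly better than — the
NIHSS reference (DeLong p = 0.22 at n = 82 test patients); and the score's
joint effect with old age exceeds additivity (AP > 0 with CI excluding 0),
i.e. a synergistic interaction, consistent with the positive age×score
structure in the generating model.

The same stages are scriptable via the `strokerecur` CLI (`simulate`,
`grade`, `fit`, `score`, `evaluate`, `interact2`, `interact3`); every stage
is byte-deterministic given its inputs and `--seed`.

## Layout

- `src/strokerecur/` — the library: `cohort` (synthetic cohorts), `grading`,
  `importance` (fusion score), `interaction` (RERI/AP/S, product-term
  models), `metrics` (ROC/DeLong/bootstrap), `cli`.
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `docs/methods.md` — modeling assumptions, parameter choices, limitations.
- `tests/` — unit, property and end-to-end statistical tests.
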