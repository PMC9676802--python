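# Methods

## Problem and pipeline

Hyposmia is an early, near-universal non-motor feature of Parkinson's disease
(PD), and 40-item odor-identification batteries (UPSIT-style: each item scored
correct/incorrect) discriminate PD patients from healthy subjects (HS) well but
are slow to administer. The package distills an abbreviated screening panel
from such a battery and evaluates it:

1. **Item ranking, five ways.** Per item, the 2×2 correct/incorrect × class
   table gives a two-sided Fisher exact p-value, a diagnostic odds ratio
   (DOR), and a single-item AUC; two joint models — L2-penalized logistic
   regression and regularized linear discriminant analysis (LDA) — rank items
   by absolute weight.
2. **Consensus voting.** Each method nominates its top *k* = 12 items; items
   nominated by at least *m* = 4 of the *M* = 5 methods form the panel. The
   combination matrix (the tabular form of an UpSet plot) records exactly
   which method subset selected each item.
3. **Panel evaluation.** PLS-DA (PLS1 regression of the 0/1 class indicator,
   threshold 0.5) and a Gini CART tree are cross-validated on the panel and on
   the full battery; all metrics come from the single pooled out-of-fold
   confusion matrix.
4. **Screening cut-off.** The panel sum score (count of correct responses) is
   thresholded as "score ≤ t ⇒ PD"; the Youden index J = sens + spec − 1
   over integer thresholds picks the operating point.

Orientation conventions, fixed throughout: responses are coded 1 = correct;
an *incorrect* response is the test-positive state for PD, so larger DOR/AUC
always mean a more discriminative item; PD = 1 in every model; reported item
numbers are 1-based.

## Synthetic cohort generator

No subject-level data are distributed, so the pipeline runs on synthetic
cohorts: per class, each item is an independent Bernoulli draw with a
class-specific probability of correct identification. The default
specification emulates the published cohort summary — 68 PD and 61 HS
subjects, expected total scores 16.8/40 (PD) and 26.6/40 (HS):

| parameter | default | rationale |
|---|---|---|
| n_PD / n_HS | 68 / 61 | study cohort sizes |
| planted items | 8 items, P(correct) 0.30 (PD) vs 0.80 (HS) | strongly discriminative screening items (per-item DOR ≈ 9.3, AUC ≈ 0.75) |
| background items | 32 items, P(correct) 0.45 (PD) vs 0.63125 (HS) | uniquely determined by the class-mean targets once the planted effects are fixed |
| planted positions | 1-based {3, 7, 8, 10, 15, 22, 30, 35} | four match the battery numbers reported for selected odors (7 banana, 8 clove, 10 coconut, 30 watermelon); the generator is indifferent to positions |
| seed | single integer, one generator stream | full reproducibility |

The published HS standard deviation is typeset as "± 507" and read as ≈5.07;
the generator treats only the means as calibration targets.

**What the generator does not emulate.** Items are conditionally independent
given class — real batteries have correlated items (shared odor qualities,
general hyposmia severity). Independence shrinks the total-score SD (≈3.1 vs
the reported 4.9) and makes the full battery *more* informative than a real
one, and it forces every background item to carry true signal (the class-mean
gap must be distributed over the 32 non-planted items). Consequences spelled
out below under "Known limitations". Passing the simulation studies therefore
shows the pipeline recovers the structure this generator plants, not that it
would select the same odors in a clinical cohort.

## Model and numerical choices

- **Fisher exact test.** Two-sided by the point-probability rule (sum of
  hypergeometric probabilities ≤ the observed table's), via
  `scipy.stats.fisher_exact`; a zero-margin (degenerate) table returns p = 1.
  The test suite checks exact agreement with a full hypergeometric enumeration
  over all tables with both class sizes ≤ 12 plus a seeded sample with margins
  up to 30 (full exhaustion to 30 would be ~244k tables for no additional
  coverage of the code path).
- **DOR.** (incorrect_PD × correct_HS)/(correct_PD × incorrect_HS); when any
  cell is zero, all four cells receive the Haldane–Anscombe +0.5 before the
  ratio, and the correction is noted in the ranking output.
- **Single-item AUC.** (TPR + TNR)/2 for the binary rule "incorrect ⇒ PD";
  equals the mid-rank Mann–Whitney AUC of the 0/1 predictor.
- **Regularization of the joint models.** Forty binary predictors on ~130
  subjects sit near linear separability, where unpenalized weights diverge and
  their order is noise. The logistic fit uses a unit L2 penalty (C = 1.0,
  intercept unpenalized, `newton-cholesky` solver, 500-iteration cap,
  tolerance 1e-8 — non-convergence raises). The LDA direction solves
  Σ_reg w = μ_PD − μ_HS with the pooled within-class covariance shrunk toward
  a scaled identity at the Ledoit–Wolf optimal intensity. We first tried
  near-vanishing penalties (λ ∝ 1/n ridge for the logistic, 1e-3·tr(Σ)/p for
  LDA); both left the fits effectively separable — |β| ≈ 10 and top-12 lists
  that dropped truly discriminative items in roughly half the replicates — so
  the defaults were moved to the standard choices above. Both remain keyword
  knobs (`C`, `shrinkage`) for sensitivity analyses.
- **Items are never standardized**: all predictors share the 0/1 scale, so raw
  absolute weights are comparable across items.
- **Tie-breaks, everywhere deterministic.** Rankings break score ties by
  ascending item number; tree splits with equal Gini gain go to the lowest
  item number; a tied leaf labels PD (a screening rule prefers sensitivity);
  the Youden cut-off tie goes to the lowest threshold (favors specificity, and
  adjacent thresholds not realized by any score define the same empirical
  rule).
- **PLS-DA** is PLS1 NIPALS (via `sklearn.cross_decomposition.PLSRegression`,
  no scaling), default 2 components — the smallest expressive choice and the
  convention for score plots; the model stores means, weights, loadings and
  the final coefficient vector so predictions are reproducible by explicit
  matrix arithmetic. Requesting more components than the centered data rank
  raises.
- **Decision tree** is an in-package greedy Gini CART on 0/1 items
  (max depth 10, min leaf 2, no pruning). It is hand-rolled because the pinned
  tie-break and leaf-score semantics above are not guaranteed by library
  trees; on tie-free data it agrees with `sklearn.tree.DecisionTreeClassifier`
  (asserted in the suite). Scores are leaf PD fractions.
- **Cross-validation** is stratified 10-fold, shuffled with an explicit seed,
  single repetition. Every subject is predicted exactly once out-of-fold;
  all metrics derive from the pooled confusion matrix (never averaged across
  folds); AUROC is the mid-rank Mann–Whitney statistic of the pooled scores.
  The original study's CV scheme and tool hyperparameters are unpublished;
  these are declared defaults, all exposed as config knobs.
- **Diagnostic metrics.** Each proportion carries the binomial standard error
  √(p(1−p)/n). An infinite LR+ (fp = 0) is an explicit flag plus the
  one-sided continuity-corrected value, never a sentinel. An undefined
  PPV/NPV (empty call margin) is reported as missing, not 0.
- **Confusion-matrix reconstruction.** Printed 2-dp sensitivity/specificity at
  known class sizes are inverted by exhaustive search over (tp, tn) using
  half-open interval membership [x − 0.005, x + 0.005), which is robust to the
  typesetting rounding convention; no-solution and multiple-solution cases
  raise with the full candidate list. Display rounding elsewhere is decimal
  half-up.

## Consensus arithmetic notes

With five exact-12 lists the item-vote total is exactly 60. The published
vote structure (4 items × 5 votes, 4 × 4, 4 × 3, 9 × 1) sums to 57, so the
original lists cannot all have had exactly 12 items (or some 2-vote items
went unreported). The implementation enforces exact-k lists and makes no
attempt to guess the discrepancy's source; the suite realizes the published
structure with unequal-size lists where needed.

## Problem sizes

Simulation studies use 50 independently seeded replicates each: planted-item
recovery at n = 100/100, the panel-vs-battery CV comparison and Youden
cut-off stability at the study sizes n = 68/61. The Fisher oracle check
enumerates ~8,100 tables exhaustively plus 300 sampled larger ones. These
sizes give binomial SEs of ≤ 7 points on the reported rates while keeping the
full suite and the acceptance script each under a minute of CPU.

## Known limitations

- Under the calibrated generator, the full 40-item battery is genuinely more
  informative than the 8-item panel (every background item discriminates, and
  item independence removes the redundancy real batteries have). A
  2-component PLS-DA, being low-variance, therefore tends to do *better* with
  all 40 items on synthetic cohorts — the opposite of the published
  comparison — while the greedy tree, which overfits with 40 candidate
  splits, reproduces the published dimension-reduction advantage (~85–90% of
  replicates). The panel-vs-battery study reports both rates; only the tree's
  is expected to clear 80%.
- The Youden cut-off, selected odors, and AUCs of the original cohort are not
  reproducible without its subject-level data; the synthetic studies check
  procedure behavior (recovery, stability, internal consistency), not those
  clinical values.
- No covariates (age, sex, smoking) are simulated — the published groups are
  matched and covariates enter no computation — and no item-response-theory
  structure is modeled.
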