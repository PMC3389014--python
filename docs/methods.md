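# Methods

## Model and procedure

`svmorph` treats two-group classification of regional brain volumes as a
small-n, moderate-P supervised learning problem: n ≈ 40 subjects, P ≈ 121
features (segmented-region volumes in mm³), plus two nuisance covariates
(age in years, sex as a 0/1 indicator). The classifier is a linear
soft-margin SVM:

    minimize over (w, b, ξ):  ½‖w‖² + C Σᵢ ξᵢ
    subject to  yᵢ(w·xᵢ + b) ≥ 1 − ξᵢ,  ξᵢ ≥ 0

solved by libsvm's SMO (reached through scikit-learn's low-level binding;
the public `SVC` estimator is coefficient-identical but pays ~45× overhead
per fit, which matters when the nested loops perform 10⁵–10⁶ fits).
Feature j's relevance is |w_j|; recursive feature elimination removes the
smallest-|w| feature first.

Accuracy estimation and feature selection are nested so that the held-out
subject influences nothing:

- **Outer loop** (one fold per subject): fit the covariate regression and
  the scaler on the n−1 training subjects; choose Q by the inner loop;
  rank, reduce, retrain; transform and predict the held-out subject.
- **Inner loop** (one fold per training subject): train on all features,
  compute one ranking, eliminate along it, predicting the inner held-out
  subject at every feature count P−1 … 1. Accuracies are pooled across
  inner folds (total correct / total predictions) at each count.

The full procedure is deterministic: no randomness enters anywhere between
the input table and the final report.

### Elimination schedule

The default schedule computes the ranking **once per fold** from the
full-feature model and eliminates along that fixed order. `rerank=True`
recomputes the ranking from each retrained model (classic SVM-RFE). Both
are exposed because the two readings of iterative elimination coexist in
the field; the fixed-rank schedule is the package default, and the outer
fold's Q-feature subset is taken from the same kind of ranking as the inner
loop used (fixed full-model ranking by default, iterative elimination under
`rerank`), keeping the two levels consistent.

### Tie rules and conventions (all deterministic, all documented in code)

- Q on a tied maximum of the inner curve: the **smallest** count
  (parsimony).
- Feature-rank ties (equal |w_j|): ascending feature index (stable sort).
- Decision value exactly 0: predicts the **positive** class.
- Positive class: configurable (`positive_label`); defaults to the
  lexicographically first group label.
- Curve range: counts P−1 … 1. The full-count accuracy is derivable but
  not part of Q selection (the full model's job is ranking; prediction
  happens after the first removal); a 0-feature model is undefined.

## Preprocessing

Covariate removal is per-feature OLS on `[1, age, sex]`, fitted by
`numpy.linalg.lstsq`; rank-deficient designs (e.g. constant covariates)
fall back to the minimum-norm solution with a logged warning, which
degrades gracefully to centering. Standardization uses the sample
(n−1) variance. A training feature with sd < 1e−12 is flagged degenerate
and mapped to 0 for every subject (rather than dropped), preserving feature
indexing across folds. Both transforms are strictly train-fitted; a
perturbation test asserts the held-out subject cannot move any fitted
parameter.

## Statistics

- **Binomial significance.** P(X ≥ n_correct) for X ~ Bin(n_total, chance),
  summed exactly via `math.comb` (no normal approximation). The chance
  level defaults to 0.5 (the conventional two-class null); the
  majority-class proportion can be passed instead.
- **ROC.** Empirical curve by descending score threshold with ties grouped
  (one point per distinct score), AUC by the trapezoid rule; tests verify
  AUC equals the concordant-pair statistic and is invariant under monotone
  score transforms. The pipeline-level ROC scores each subject by the
  decision value of the fold that held it out.
- **Region summaries.** Per-group five-number summaries with
  linear-interpolation quartiles, plus the single-region AUC using the raw
  volume as score.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `cost` (C) | 1.0 | soft-margin cost; the default of the common libsvm interfaces. Features are standardized upstream, so C=1 is a reasonable scale; no internal rescaling happens inside the classifier. |
| `tol` | 1e−3 | SMO stopping tolerance (libsvm default). |
| `chance` | 0.5 | binomial null success probability. |
| `rerank` | off | iterative re-ranking instead of the fixed per-fold ranking. |
| `correct_covariates` | on | age/sex residualization; off exists only to demonstrate confound leakage. |

## Synthetic cohorts

The generator draws, per subject i and region j:

    volume_ij = baseline_j + β_age,j·age_i + β_sex,j·sex_i
              + effect·σ_j·group_i + ε_ij,   ε_ij ~ N(0, σ_j²)

with baselines log-uniform on [500, 20000] mm³ (the span from small
subcortical structures to large cortical parcels), σ_j = 8% of baseline
(typical between-subject variability of regional volumes), age slopes of
−0.2% of baseline per year (mild global atrophy), a +1% male offset, group
ages N(45.47, 9.47²) vs N(43.80, 9.35²) truncated at 18, sex ~
Bernoulli(0.45), and default group sizes 19/20 with 121 regions and 5
planted discriminative regions — the shape of the cohort the pipeline was
designed around. `effect` is the standardized group difference of a planted
region after confound removal. Everything is deterministic given the seed.

What the generator does **not** emulate: anatomical covariance between
regions (volumes are conditionally independent), hemispheric symmetry,
scanner/site effects, non-Gaussian tails, and measurement error correlated
with head size. Passing tests on synthetic cohorts therefore demonstrate
the pipeline's statistical machinery (no leakage, confound removal,
calibrated nulls, recovery of independent planted signals), not performance
on real morphometry, where correlated features typically make both
classification easier and selection less stable.

## Behaviour worth knowing about

- **Leave-one-out is pessimistic under the null.** With balanced groups and
  no signal, the training fold is always imbalanced against the held-out
  subject's class, so null accuracies average below 0.5 (measured ≈
  0.39–0.47 across feature counts at n=20, P=10). Chance-level checks in
  the tests use bands that account for this; it also means the binomial
  test at chance 0.5 is conservative.
- **Strict consensus is fragile by construction.** A region enters the
  consensus map only if it survives selection in *every* outer fold. Folds
  whose inner curve peaks at small Q (favoured by the parsimony tie-break)
  prune genuine signal regions from the intersection: on 20+20-subject
  cohorts with 5 independent planted regions at effect 2.0, planted regions
  reach per-fold selection frequencies of ~0.9–1.0, yet the full
  intersection rarely equals all five (and raising the effect size shrinks
  Q further, since single features then suffice). The per-fold
  selection-frequency table in the report is the robust view; the strict
  consensus list is reported alongside it.

## Problem sizes used in the shipped checks

Unit and property tests run on cohorts of ≤ 40 subjects and ≤ 30 regions;
the end-to-end replicate checks use 25 cohorts of 20+20 subjects × 30
regions, and the oracle-equivalence checks use 20 random cohorts of ≤ 8
subjects × ≤ 4 features against an explicit-loop re-implementation.
`scripts/acceptance.py` runs the full default scale (39 subjects × 121
regions). These sizes keep a complete run in the minutes range on one CPU
while exercising every code path at the cohort scale the package targets.
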