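# Methods

## The problem

Binary classification studies on small tabular datasets (a few dozen to a
few hundred observations — common in education research, psychology, and
clinical pilot studies) face two coupled evaluation hazards. First,
hyperparameter tuning and feature selection leak information into the
performance estimate unless they are re-run inside every training
partition. Second, even a leakage-free score says nothing about how likely
an equally good score would have been under *no* feature–label dependency:
on 25–50 observations, a respectable-looking MCC arises by chance
surprisingly often. `rncv` packages the two corresponding remedies —
repeated nested cross-validation and a label-permutation significance test
— behind one consistent machinery.

## Evaluation procedure

**Nested CV.** An outer stratified `n_outer`-fold CV (default 10) estimates
generalisation performance. On each outer training partition an inner
stratified `k_inner`-fold CV (default 5) scores every combination of an
exhaustive hyperparameter grid with the full pipeline re-fitted per inner
fold; the best combination (ties: first in declared grid order) is refitted
on the whole outer training partition and scored once on the held-out fold.
The nCV score is the mean over outer folds. Training and evaluation always
use the *same* metric, and the positive class is always the minority class
of the full dataset (sorted-first class when exactly balanced).

**Repeated nested CV.** The nCV is repeated under `r` seeds (default 5),
each seed governing the fold assignments and all stochastic pipeline stages
of that repeat. The rnCV score is the arithmetic mean of the repeat means —
an exact identity asserted in the test suite, not an approximation. The
repeat min/max/sd quantify seed sensitivity, which grows sharply as `n`
shrinks.

**Pipeline.** Fixed stage order inside every training partition: mutual-
information feature ranking (optional) → standardisation → random
oversampling (optional) → C-SVC. Test rows pass only through the frozen
transforms; nothing is ever fitted on, or oversampled in, a test partition.

* *Feature ranking* uses a plug-in MI estimate on the contingency table of
  each feature with the label, after discretising continuous columns into
  `min(10, #unique)` quantile bins. This estimator is deterministic (no
  noise injection, ties break to the lower column index), which we value
  above estimator efficiency here because ranking stability across grid
  combinations is what the search needs. It is a design choice, not the
  only reasonable MI estimator for mixed-type data.
* *Standardisation* uses training-partition means and population (ddof=0)
  standard deviations; zero-variance columns are centred only. Outliers are
  deliberately not removed; standardisation rather than min-max scaling
  limits their influence.
* *Random oversampling* duplicates minority training rows with replacement
  until counts are equal. It defaults off: the synthetic study datasets are
  balanced by construction, so only fold-level ±1 imbalances exist. The CLI
  enables it by default for real CSV data. SMOTE-style interpolation is
  intentionally out of scope.
* *SVM.* `C`, `gamma` (numeric or `scale` = 1/(d·var), `auto` = 1/d,
  resolved on the post-standardisation data) and the kernel
  (`linear | rbf | poly | sigmoid`) form the default 36-combination grid
  `C ∈ {0.1, 1, 10} × gamma ∈ {0.1, scale, auto} × kernel`; with feature
  selection on, `n_features_to_select ∈ {10, 15, 20, 25, 30}` joins the
  grid (180 combinations). Defaults without tuning: `C=1, gamma=scale,
  kernel=rbf`, 10 selected features.

**Ablations.** Four variants: full, no feature selection, no tuning
(ranking still runs, the selection count is fixed at its default — the
*search* is ablated, not the stage), and neither (no inner CV at all).

## Permutation test

For one dataset, `N` label-permuted copies are generated once
(whole-dataset uniform permutation; class counts, hence the positive class
and stratification feasibility, are preserved). Every copy is evaluated
with the *same* repeat seeds and fold machinery as the original. The
empirical probability that the null hypothesis is true uses the add-one
form

    p = (1 + #{permuted score ≥ original score}) / (1 + N),

so p is never 0, its floor is 1/(N+1) (2% at two decimals for N=50), and
ties count conservatively against the original. Because the permutations
are shared, three estimates are directly comparable: `p_rncv` (original
rnCV mean vs permuted rnCV means), one `p_ncv` per repeat seed, and their
average. Averaging repeats *before* comparison shrinks the variance on both
sides of the comparison, so `p_rncv` is systematically ≤ the averaged
per-seed probability — the practical argument for testing with the rnCV
directly rather than averaging per-seed tests.

Small `N` (25–50, the package defaults for sweeps and single-dataset
reports) over-estimates p and is suitable for qualitative comparisons; for
publication-grade p-values use `N ≥ 999`.

## Synthetic data generator

`generate_balanced_gaussian` draws class 1 (`⌊n/2⌋` rows) i.i.d. from
N(0, 1) in every feature and class 2 (the remainder; one more row for odd
`n`) from N(0.2, 1), then shuffles rows — a deliberately weak, isotropic
signal (Mahalanobis separation 0.2·√d ≈ 0.63 at d = 10) so that evaluation
behaviour near the detection limit is visible. What it does *not* emulate:
feature correlations, mixed types, outliers, label noise, or class
imbalance. Passing tests on this ensemble validate the evaluation
machinery, not classifier performance on any real domain; the CSV loader
and oversampler exist precisely because real data differ in these ways.

Ensembles derive one child seed per dataset from a master seed; all
experiment-level randomness (repeat seeds, permutation seeds, bootstrap
resamples) flows from explicit integer seeds through `SeedSequence`-based
derivation, so every table cell is bit-reproducible from one integer.

## Numerical and implementation choices

* Metrics are computed from exact confusion counts; precision, recall, F1,
  MCC and kappa return 0 on a vanished denominator (constant predictions
  give MCC 0, keeping permutation scores defined on every fold). AUC uses
  the Mann–Whitney mid-rank formulation on decision values (AUC on hard
  labels would collapse onto balanced accuracy). MCC/kappa are mapped to
  [0, 1] by (x+1)/2 when metrics are compared on a common scale.
* Stratified folds deal shuffled within-class indices round-robin with a
  cursor carried across classes: per-fold class counts and total fold sizes
  each differ by at most 1. Infeasible stratification (a class smaller than
  `k`) raises instead of silently reducing `k`.
* Averaged confusion matrices have fractional entries; their entries sum to
  `n / n_outer` because outer folds partition the data.
* SVM fits run through a minimal wrapper over scikit-learn's libsvm binding
  rather than the `SVC` estimator: at these training-set sizes (tens of
  rows) estimator-level validation dominates runtime by ~10×, and a full
  ensemble study performs millions of fits. The wrapper is pinned to `SVC`
  by an exact-agreement test across kernels, gamma modes, C values and row
  orders.
* Bootstrap CIs are percentile intervals of the mean over datasets
  (B = 1000 resamples by default; the interval, like any percentile
  bootstrap, is approximate for very small ensembles).

## Problem sizes used in the shipped experiments

The test suite runs the ensemble study at 10 datasets per condition and
the acceptance script at 16 (n = 50, N = 25 permutations, 5 repeats,
36-combination grid); the null-calibration study uses 50 datasets (n = 40,
N = 25, single-seed nCV, untuned pipeline — the calibration property of a
permutation test does not depend on the model inside). These are the
package's chosen simulation sizes: large enough for the qualitative
properties (probability level, nCV ≥ rnCV ordering, type-I-error band,
variance trends) to be stable, small enough to re-run routinely. Note that
the mean of 10–20 permutation probabilities still carries a standard error
of about 0.05–0.07 at n = 50; single-run means scatter accordingly around
the large-ensemble value. Larger ensembles (100 datasets per size, the
full 25–330 size sweep) use the same code via
`rncv.experiments.run_sweep`.

## Known limitations

* The binned plug-in MI estimator underestimates MI for strongly continuous
  dependencies; it is used for *ranking*, where only the order matters.
* The permutation test assumes exchangeability of labels under the null —
  appropriate for i.i.d. rows, not for grouped or time-ordered data.
* No multiple-testing correction is applied when several metrics are
  reported side by side; the report is comparative, not confirmatory.
* Probabilities at N = 25–50 are coarse (grid 1/(N+1)) and upward-biased;
  they order methods correctly but should not be quoted as precise
  p-values.
* The one-hot encoder operates on the whole dataset before splitting. This
  is a fixed re-encoding of observed categories, not a fitted statistic,
  but with extremely rare categories it can still make folds aware of
  categories absent from their training rows.
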