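# Methods

## The selection problem

Given m samples with binary disease labels and n methylation beta values
per sample (fractions in [0, 1], one per CpG site, n ≫ m), the goal is a
small CpG panel on which a classifier separates the classes well out of
sample. The pipeline treats the classifier φ as a black box and uses its
repeated-holdout test accuracy as the only selection signal — a wrapper
approach, chosen because there is no a-priori reason to expect the
methylation–disease relationship to be linear or marginal.

Accuracy of a feature set is always estimated the same way: draw k
train/test partitions (default k = 10; train fraction 2/3, stratified),
train φ on the training slice, score the test slice, average the test
accuracies. One partition plan is drawn per selection run and reused for
every feature and every candidate subset (common random numbers), so
that comparisons between features reflect the features and not split
noise. The train-set size is round-half-up of `train_fraction × m`, so a
50/50 split of an odd cohort gives the training set the extra sample.

## Stage 1: per-CpG screening

Each CpG is scored individually: MF_i is the mean holdout accuracy of φ
trained on that single column. CpGs with MF_i below the cutoff MFc are
excluded; a CpG exactly at the cutoff is retained. Two cutoff modes:

* **Explicit MFc** (default 0.70): retains exactly `{i : MF_i ≥ MFc}`.
* **Quantile / top-fraction**: retains the top `round(q·n)` CpGs by MF
  rank, ties at the boundary broken by input order. The rank-based form
  matters in practice: under class imbalance every uninformative CpG
  scores exactly the majority-class rate, so a value-threshold at the
  (1−q) quantile can degenerate to retaining everything. The recorded
  cutoff is the smallest retained MF.

Screening dominates the compute budget (n single-feature fits × k
partitions), so for the closed-form backends (logistic, threshold stub,
majority stub) all n fits of a partition are solved simultaneously by
batched solvers; a 76 × 2,000 screen takes well under a second on one
CPU. The MLP backend falls back to a per-CpG loop (optionally
parallelised with joblib); results are identical for any worker count
because every CpG's computation is seeded independently of scheduling.

## Stage 2: randomized greedy backward elimination

From the retained list with incumbent accuracy MF\*, each iteration
removes one CpG chosen uniformly at random, re-estimates the candidate
accuracy MF\*\* on the identical partitions, and accepts the removal iff
MF\*\* > MF\* strictly — ties reject, so a redundant duplicate feature
is only dropped if doing so actually helps. Consequences asserted by the
test suite on every run: accepted accuracies increase strictly, the list
shrinks by exactly one per acceptance, and every historical list is a
subset of its predecessor.

Stopping: `itermax` attempts (every attempt counts, accepted or not), or
incumbent accuracy ≥ `mf_target`, or the list reaching
`min_subset_size` (default 1). The target is interpreted as "stop once
the desired accuracy level has been achieved": since the incumbent never
decreases, a lower bound is the only direction under which an accuracy
target can act as a stopping rule. The incumbent accuracy is carried
forward from the accepted candidate rather than re-estimated;
`reevaluate_incumbent=True` re-estimates it each iteration (a no-op for
deterministic backends, a variance-control option for stochastic ones).

The search is greedy and randomized: it finds a locally irreducible
subset along one random removal trajectory, not a global optimum, and
different seeds legitimately yield different panels of similar accuracy.
No worsening moves, multi-feature moves or forward steps are taken.

## Classifier backends

* **mlp** — the reference configuration: `n_hidden_layers` × 100
  sigmoid units, one sigmoid output thresholded at 0.5, binary
  cross-entropy, at most 1000 iterations. Four hidden layers is the
  default depth (accuracy plateaus there in the motivating application).
  Training uses scikit-learn's lbfgs quasi-Newton solver; the named
  optimizer is recorded in the spec for transparency. Raw beta features
  are used unscaled.
* **logistic** — ridge-penalized logistic regression (penalty 1.0 on
  the weights, intercept free — the scikit-learn C=1 convention) fitted
  by damped Newton/IRLS to gradient tolerance 1e-8. Features are
  standardized internally with training-set statistics: on the raw
  [0, 1] beta scale a biologically large shift (~0.25) needs coefficients
  of order 30+, which a unit ridge crushes — empirically the unscaled
  fit collapses to the majority rule and planted CpGs become
  indistinguishable from noise. Standardization restores the intended
  behaviour while keeping the standard penalty convention; the test
  suite cross-checks coefficients and predictions against
  `sklearn.linear_model.LogisticRegression` to 1e-6. This backend is the
  pipeline default for both stages: single-feature inputs cannot exploit
  depth, and the batched solver keeps desk-scale runs interactive.
* **threshold_stub / majority_stub** — deterministic closed forms
  (nearest class-centroid, which on one feature is the midpoint-of-
  class-means cut; constant majority-class prediction, training ties to
  class 1). They exist so the selection stages can be verified against
  explicit-loop brute-force oracles to 1e-12.

All backends emit a score in [0, 1]; class 1 is called when the score
is ≥ `decision_threshold` (default 0.5). Training on single-class data
yields a constant predictor (with a logged warning for mlp/logistic), so
unstratified small-cohort splits degrade gracefully instead of failing.

## Synthetic data generator

The generator emulates the shape of the motivating cohort: default 24
controls + 52 cases (the pre-manifest companion scenario: 24 vs 19, with
a smaller default shift of 0.15 reflecting weaker pre-symptomatic
signal), 2,000 CpGs standing in for ~485k at desk scale, 25 informative.
Each CpG draws from a Beta distribution parameterized by mean and
concentration c (shapes `a = mean·c`, `b = (1−mean)·c`; default c = 30
gives an array-like per-CpG standard deviation of ~0.09 at mid-range
means). Baseline means are uniform on (0.1, 0.9); informative CpGs shift
the case mean by `effect` (default 0.25, i.e. roughly 2.9 within-class
standard deviations — a strong differential-methylation signal), sign
randomized per CpG and flipped if the shifted mean would leave
(0.02, 0.98); if neither direction fits, the parameters are rejected.

What it does **not** emulate: Type I/II probe chemistry, batch and
chip-position effects, cell-composition confounding, age/sex structure,
and — importantly — correlation between CpGs (every probe is generated
independently). Passing tests therefore demonstrate that the algorithm
recovers planted marginal signal and that the evaluation is honest; they
do not demonstrate robustness to the correlated, confounded structure of
real array data.

## Evaluation design

Wrapper selection optimizes the very quantity it reports, so its
in-search accuracy is biased upward, and re-splitting the same samples
after selection does not remove the bias (the selected features'
spurious associations are properties of the whole sample). The pipeline
therefore reports two numbers:

* **Nested held-out metrics** (the headline): for each outer fold the
  samples are split once (same train fraction); both selection stages
  run on the development part only; φ is trained on it and scored on the
  untouched test part; means are taken over folds (default 5),
  partitions with an undefined metric (empty denominator) are excluded
  and counted. With no planted signal this estimate sits at chance, which
  the acceptance suite verifies.
* **Selection-protocol report**: repeated-holdout metrics of the final
  panel over fresh splits of all samples — the protocol under which the
  panel was found, labelled as optimistic.

The final panel itself comes from running both stages on all samples,
using the data fully once the unbiased estimate is in hand. Sensitivity
is the detection rate among cases (class 1 positive), specificity the
true-negative rate among controls; undefined metrics are reported as
NaN, never 0.

## Numerical and reproducibility choices

* All randomness derives from one run seed through named substreams
  (synthesis, inner plans, classifier, search, outer splits, report
  plan) via `SeedSequence`, so each stage is independently reproducible
  and derived seeds stay below 2^31.
* Newton steps are damped by backtracking on the penalized loss; the
  ridge keeps the Hessian positive definite for p > n and separable
  data. Batched and general solvers agree to ~1e-7 and are tested to.
* Beta matrices are written with `%.17g` and parsed with exact float
  conversion, so write → read is bit-identical (pandas' fast to_numeric
  path can be off by one ulp and is used only for malformed-cell
  detection).
* Stratified splits allocate per-class training slots by largest
  fractional remainder (ties to the larger class, then the lower
  label); values exactly 0 or 1 are valid beta values; missing values
  are handled by dropping the CpG column, never the sample.
* Test and acceptance problem sizes (2,000 CpGs, 5–20 seeds, itermax
  200–300, 400-CpG null scenarios) are the package's chosen desk-scale
  study conditions; the algorithm itself has no size limits beyond
  memory.

## Known limitations

Binary labels only (sub-cohorts are handled by filtering samples before
input); covariates (age, body-mass index) are carried through I/O but
not modelled; no multiple-testing control is applied in stage 1 — the
cutoff is an accuracy threshold, not an error-rate guarantee; the greedy
search offers no optimality certificate; and the MLP backend at
reference depth is computationally heavy for full-array screening, which
is why the logistic backend is the documented screening default.
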