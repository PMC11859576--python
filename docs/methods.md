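# Methods

This note documents the models and procedures implemented in `imbga`, the
assumptions behind them, the parameters that matter, and the design choices
made where the design was genuinely open.

## Problem setting and label convention

All stages operate on a tabular dataset `(X, y)` with `y ∈ {0, 1}` where
**0 is the minority class of interest** (the rare clinical event) and 1 the
majority. The convention is fixed package-wide; readers validate it and the
evaluation module scores the minority class as the positive class by
default. Imbalance is quantified by the unbalanced ratio
`UR = n₁ / n₀ > 1`, displayed to 3 decimals.

Min-max normalization `u = (f − f_min)/(f_max − f_min)` is fit on training
data and reapplied to held-out data via stored per-feature parameters.
Constant features (zero range) map to 0 with a warning; the degenerate case
has no canonical answer and 0 keeps the output inside `[0, 1]`.
Missing-value policy: columns with more than 20% missing are dropped, then
remaining incomplete rows are dropped; both actions are logged. The 20%
threshold is a package choice — any fixed cutoff is defensible and this one
retains most columns in typical screening data.

## Hybrid resampling

**Oversampling.** Each synthetic minority sample is
`u_new = u_i + s·(u_ij − u_i)` with `s ~ U(0,1)` and `u_ij` drawn uniformly
from the `m = 5` nearest minority neighbors of `u_i`. Neighbor search runs
among minority samples only, on min-max-normalized features, so that no
single large-scale feature dominates the metric; interpolation happens in
the original feature space (the map is affine, so the two are consistent).
Sampling continues until the minority count reaches
`ceil(target_ratio × n₁)`; the default `target_ratio = 1` (full balance) is
the natural stopping point when no other count is prescribed. Every
synthetic point is by construction a convex combination of two original
minority points — a property the test suite checks with a
segment-membership oracle at tolerance 1e-9.

**Cleaning.** A Tomek link is a cross-class pair whose members are each
other's single nearest neighbor. The cleaner removes the majority member of
every link and rescans, iterating to a fixed point (a brute-force O(n²)
scan finds zero links afterwards). Deleting the majority member preserves
scarce minority information; a `policy="both"` variant removes both. If a
pass would empty a class, cleaning stops with a warning rather than
destroying the dataset. Distance ties break toward the lowest row index so
the procedure is deterministic. The interpretation of "neighboring samples
of different class at one step distance" as Tomek links is the canonical
threshold-free construction for boundary cleaning; it is an interpretation,
and it is the one this package commits to.

**Leakage groups.** Interpolated samples are near-copies of their base
sample. Any later cross-validation that puts a synthetic point in a
validation fold while its base (or a sibling interpolant) sits in the
training fold is optimistically biased. The sampler therefore tags every
row with a *group id* — original rows get their own id, synthetic rows
inherit their base sample's — and every CV split downstream uses a
stratified **group-aware** splitter when groups are present. Measured on a
UR ≈ 50 scenario, plain stratified folds report out-of-fold AUC ≈ 0.99
where group-aware folds report ≈ 0.93 and held-out AUC is ≈ 0.75: the
grouping removes most, though not all, of the optimism (a synthetic point's
*second* parent may still land in another fold; tracking only the base
parent keeps the bookkeeping simple and already closes most of the gap).

## F-score feature selection

With `n⁺` majority (label 1) and `n⁻` minority samples, the standard score
of feature *i* is

    F_i = [(Ū_i⁺ − Ū_i)² + (Ū_i⁻ − Ū_i)²] / [s²_i⁺ + s²_i⁻]

where `Ū_i` is the overall mean and `s²_i±` are within-class sample
variances (n−1 denominators). The imbalance-aware variant `F′_i` uses only
`s²_i⁺` in the denominator. Consequences worth knowing: `F′_i ≥ F_i`
whenever the minority variance is positive; both scores are invariant to
adding a constant to a feature; both are undefined when the denominator is
zero, in which case the package returns `+inf` with a warning — degenerate
perfectly-separating features rank above all finite scores, ties breaking
by column order.

The wrapper loop ranks features, then evaluates the top-*k* subset for
`k = 1 … max_dim` by stratified-CV AUC of a configurable learner (AdaBoost,
bagging or logistic) and returns the argmax, ties going to the smallest *k*
(parsimony). By default the ranking is **recomputed inside each training
fold** so the reported curve carries no selection bias; a
`leaky_single_pass` flag restores the simpler rank-once flow for
comparison. On planted-feature scenarios the curve is an inverted U: AUC
rises while genuine features are added and falls as noise dilutes the
learner.

## Stacking ensemble and genetic search

The first-layer pool holds exactly ten heterogeneous probabilistic
classifiers, in fixed order: SVM (RBF), bagging, random forest, logistic
regression, k-NN, gradient-boosted trees, Gaussian naive Bayes, XGBoost,
Gaussian-process classifier, AdaBoost. Two slots in the original panel name
model families without tabular formulations (Markov random field, deep
confidence network); they are filled by logistic regression and k-NN to
preserve ten genuinely heterogeneous members, and the pool is fully
configurable. The SVM and GP members wrap their solver in a stratified
subsampler (800 and 250 training rows respectively) because both scale
superlinearly (the GP cubically) and the pool must stay usable on
several-thousand-row resampled datasets; every other member trains on the
full data. The GP member's configuration documents the standard GP
classification quantities — kernel matrix, noise variance ψ², probit-style
link — while the solver is scikit-learn's `GaussianProcessClassifier`
(Laplace approximation with a logistic link, the standard practical
stand-in for probit). The AdaBoost member's additive contract — staged
decision values are cumulative weight-normalized sums of weak-learner votes
— is asserted in a test rather than re-derived.

**Stack construction** (`fit_stack`): for the selected members, stratified
(group-aware) K-fold out-of-fold minority-class probabilities over the
training set form the meta-learner design matrix; an L2-regularized
logistic regression is fit on it; the members are then refit on the full
training data for deployment. Defaults: 5 folds, `C = 1`.

**Fitness** (`StackFitness`): chromosome fitness is the *nested*-CV AUC of
the stacked model — per outer fold, an inner OOF matrix is built on the
outer-train only, the meta-learner is fit there, and the members (refit on
the outer-train) score the untouched outer-test. An earlier single-level
variant that cross-validated the meta-learner over one shared OOF matrix
was measurably optimistic (label-permuted data scored CV AUC ≈ 0.57 because
first-layer models had seen the evaluation rows); the nested scheme scores
≈ 0.5 on permuted labels, which the test suite asserts. A member's OOF
columns do not depend on which other members are selected, so all member
fits happen once per dataset and each chromosome evaluation costs only a
few small logistic fits — this is what makes exhaustive enumeration over
all 2¹⁰−1 subsets tractable as an oracle for the GA.

**GA** (`ga_optimize`): generations of evaluate → elitism(1) → roulette
selection (`P_i = fit_i / Σ fit_j`; all-zero fitness degrades to uniform
with a warning) → multipoint crossover (default 2 cut points, rate 0.8) →
per-bit mutation (rate 0.05, all-zero chromosomes repaired by setting one
random bit). Defaults — population 20, 15 generations — were fixed a
priori as ordinary GA practice for a 10-bit space; elitism of one
guarantees the best-ever trace is non-decreasing. On shared fitness
landscapes the GA lands within 0.01 AUC of full enumeration.

**Grid search** enumerates the full Cartesian hyperparameter grid with
stratified CV on AUC (or accuracy), ties resolved by enumeration order.

## Synthetic data generator

The generator emulates the statistical structure of small clinical cohorts:
minority and majority classes are unit-variance Gaussian clusters whose
mean vectors differ by `class_separation` (Euclidean norm, pooled-SD units)
in the informative subspace — so the Bayes AUC has the closed form
`Φ(d/√2)`, e.g. 0.86 at the default `d = 1.5`, a deliberately moderate
overlap. Redundant features are `ρ·parent + √(1−ρ²)·noise` mixes
(default ρ = 0.7), noise features are independent standard normal, labels
can be flipped at a configurable rate (default 0 — presets carry their
overlap in the separation parameter), and an optional biomarker-ratio
feature `f_a/(f_b + 5)` mimics ratio constructs such as VEGFR-1/PGF with
the denominator shifted away from zero. Presets reproduce published cohort
shapes: 392/1,695 (UR 4.324), 86/2,008 (UR 23.349), 122/1,958 (UR 16.049)
and a 25-feature screening cohort 42/2,136 (UR 50.86).

What the generator does *not* emulate: mixed continuous/categorical
variables, non-Gaussian marginals, missingness mechanisms, longitudinal
gestational trajectories, or realistic biomarker distributions. Passing
tests on this generator demonstrates that the algorithms behave as
specified under their own assumptions — not that the pipeline attains any
particular performance on real clinical data.

## Evaluation

`classification_report` computes accuracy, precision, recall and F-score at
a threshold (default 0.5 — no operating point is canonical, and 0.5 is the
neutral choice on a balanced-trained probability) with the minority class
as positive, plus the threshold-free ROC/AUC by trapezoidal integration.
AUC equals the Mann-Whitney pair-ordering probability with ties at half
credit; the suite asserts this equivalence against a pair-counting oracle
and the label-flip identity `AUC₀ = 1 − AUC₁`.

## Benchmark scales and known limitations

- The end-to-end directional comparison (stacked pipeline vs. a raw-data
  RBF-SVM on the identical split) is run on a UR = 20 scenario with 150
  minority / 3,000 majority samples over 10 seeds. At this scale a held-out
  split contains 45 minority points and a sign test across seeds has power.
  On the 42-minority screening-cohort shape the same comparison is
  dominated by evaluation noise (13 held-out minority points, AUC sd
  ≈ 0.08): the package will run it, but no directional conclusion is
  statistically meaningful there, and the test suite does not pretend
  otherwise.
- GA fitness differences between good subsets are typically within CV
  noise; the GA is a subset-search device, not a guarantee that the
  returned subset is uniquely best.
- Group-aware CV tracks only the base parent of each synthetic point;
  residual optimism from second parents remains (measured ≈ 0.05–0.15 AUC
  between fitness and held-out performance at UR 50).
- Tomek-link cleaning assumes meaningful Euclidean geometry; it is applied
  after normalization and is not suited to one-hot-dominated spaces.
- The wrapper's per-fold reranking makes its AUC curve honest but means the
  reported `selected_features` (from the full-data ranking) can differ
  marginally from any single fold's ranking.
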