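"""GA-optimized heterogeneous stacking ensemble.

Architecture
------------
The first layer is a pool of ten heterogeneous probabilistic classifiers; a
length-10 bitstring chromosome selects which members enter the ensemble.
Each selected member contributes a column of out-of-fold (OOF) predicted
probabilities for the minority class, produced by stratified K-fold CV over
the training set, so the second layer never sees in-fold predictions.  A
regularized logistic meta-learner P(v=1|u) = 1/(1+exp(-w'ᵀu)) fuses the
columns.

A genetic algorithm searches the 2¹⁰-1 chromosome space: fitness is the
stacked model's CV AUC, selection is fitness-proportional roulette,
variation is multipoint crossover and per-bit mutation, and one elite is
carried over each generation.  Because a member's OOF column does not
depend on which other members are selected, the ten columns are computed
once per dataset and every chromosome evaluation reduces to a cheap
logistic fit — this makes exhaustive enumeration over all 1,023 subsets
tractable as a cross-check of the GA.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, WhiteKernel
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from imbga.core_data import Dataset

CHROMOSOME_LENGTH = 10


# ---------------------------------------------------------------------------
# chromosome and GA configuration


@dataclass
class Chromosome:
    """Length-10 bitstring; bit k retains (1) or deletes (0) pool member k."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=int)
        if self.bits.shape != (CHROMOSOME_LENGTH,):
            raise ValueError(f"chromosome must have {CHROMOSOME_LENGTH} bits")
        if not np.all(np.isin(self.bits, (0, 1))):
            raise ValueError("chromosome bits must be 0 or 1")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def selected_indices(self) -> np.ndarray:
        return np.nonzero(self.bits)[0]

    def key(self) -> tuple[int, ...]:
        return tuple(int(b) for b in self.bits)


@dataclass
class GAConfig:
    population_size: int = 20
    generations: int = 15
    crossover_points: int = 2
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    rng_seed: int = 0
    fitness_metric: str = "auc"

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.crossover_rate <= 1 or not 0 <= self.mutation_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.crossover_points >= CHROMOSOME_LENGTH:
            raise ValueError("crossover_points must be < chromosome length")
        if self.fitness_metric not in ("auc", "accuracy"):
            raise ValueError("fitness_metric must be 'auc' or 'accuracy'")


@dataclass
class GPConfig:
    """Gaussian-process member contract.

    The GP classifier models a latent function with the given kernel plus
    observation noise of variance ``noise_variance`` (ψ²), squashed through
    a sigmoidal link to class probabilities.  The solver is scikit-learn's
    ``GaussianProcessClassifier`` (Laplace approximation, logistic link —
    the standard practical stand-in for the probit link, with which it is
    near-indistinguishable after rescaling).
    """

    length_scale: float = 1.0
    noise_variance: float = 1e-2
    link: str = "probit"

    def __post_init__(self) -> None:
        if self.noise_variance < 0:
            raise ValueError("noise variance must be >= 0")

    def kernel(self):
        return RBF(length_scale=self.length_scale) + WhiteKernel(
            noise_level=self.noise_variance
        )


# ---------------------------------------------------------------------------
# classifier pool


class SubsampleClassifier(BaseEstimator, ClassifierMixin):
    """Fit the base estimator on a stratified random subsample of at most
    ``max_train`` rows.  Used for members whose training cost grows
    super-linearly (SVM, Gaussian process) so the pool stays usable on
    several-thousand-row resampled datasets."""

    def __init__(self, base=None, max_train: int = 500, random_state: int = 0):
        self.base = base
        self.max_train = max_train
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.model_ = clone(self.base)
        if "random_state" in self.model_.get_params():
            self.model_.set_params(random_state=self.random_state)
        if len(y) > self.max_train:
            rng = np.random.default_rng(self.random_state)
            idx = []
            for cls in np.unique(y):
                cls_idx = np.nonzero(y == cls)[0]
                n_take = max(2, int(round(self.max_train * len(cls_idx) / len(y))))
                n_take = min(n_take, len(cls_idx))
                idx.append(rng.choice(cls_idx, size=n_take, replace=False))
            idx = np.sort(np.concatenate(idx))
            X, y = X[idx], y[idx]
        self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(X)

    def predict(self, X):
        return self.model_.predict(X)


@dataclass
class ClassifierSpec:
    name: str
    factory: "callable"
    param_grid: dict = field(default_factory=dict)

    def build(self, rng_seed: int = 0, **params):
        est = self.factory(rng_seed)
        if params:
            est.set_params(**params)
        return est


@dataclass
class ClassifierPool:
    """Exactly ten heterogeneous probabilistic classifiers, in fixed order.

    Every member must expose ``predict_proba`` with outputs in [0, 1].
    """

    members: list[ClassifierSpec]

    def __post_init__(self) -> None:
        if len(self.members) != CHROMOSOME_LENGTH:
            raise ValueError(
                f"pool must have exactly {CHROMOSOME_LENGTH} members, "
                f"got {len(self.members)}"
            )

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.members]


def default_pool(gp_config: GPConfig | None = None) -> ClassifierPool:
    """The default ten-member heterogeneous panel.

    SVM, bagging, random forest, logistic regression, k-NN, gradient-boosted
    trees, Gaussian naive Bayes, extreme gradient boosting, Gaussian process
    and AdaBoost.  The SVM and GP members train on stratified subsamples
    (``SubsampleClassifier``) to keep cubic-cost solvers tractable; every
    other member trains on the full data.
    """
    gp_config = gp_config or GPConfig()
    members = [
        ClassifierSpec(
            "svm",
            lambda seed: SubsampleClassifier(
                SVC(kernel="rbf", probability=True, random_state=0),
                max_train=800,
                random_state=seed,
            ),
            {"base__C": [0.5, 1.0, 5.0]},
        ),
        ClassifierSpec(
            "bagging",
            lambda seed: BaggingClassifier(n_estimators=25, random_state=seed),
            {"n_estimators": [10, 25, 50]},
        ),
        ClassifierSpec(
            "random_forest",
            lambda seed: RandomForestClassifier(n_estimators=60, random_state=seed),
            {"n_estimators": [30, 60, 120]},
        ),
        ClassifierSpec(
            "logistic",
            lambda seed: LogisticRegression(max_iter=1000),
            {"C": [0.1, 1.0, 10.0]},
        ),
        ClassifierSpec(
            "knn",
            lambda seed: KNeighborsClassifier(n_neighbors=7),
            {"n_neighbors": [3, 7, 15]},
        ),
        ClassifierSpec(
            "gbdt",
            lambda seed: GradientBoostingClassifier(
                n_estimators=60, max_depth=2, random_state=seed
            ),
            {"n_estimators": [30, 60]},
        ),
        ClassifierSpec("naive_bayes", lambda seed: GaussianNB(), {}),
        ClassifierSpec(
            "xgboost",
            lambda seed: XGBClassifier(
                n_estimators=60,
                max_depth=3,
                random_state=seed,
                verbosity=0,
                eval_metric="logloss",
            ),
            {"n_estimators": [30, 60]},
        ),
        ClassifierSpec(
            "gp",
            lambda seed: SubsampleClassifier(
                GaussianProcessClassifier(kernel=gp_config.kernel(), random_state=0),
                max_train=250,
                random_state=seed,
            ),
            {},
        ),
        ClassifierSpec(
            "adaboost",
            lambda seed: AdaBoostClassifier(n_estimators=40, random_state=seed),
            {"n_estimators": [20, 40, 80]},
        ),
    ]
    return ClassifierPool(members)


# ---------------------------------------------------------------------------
# stacking


def _minority_proba(est, X: np.ndarray) -> np.ndarray:
    """Probability column for the minority class (label 0)."""
    col = list(est.classes_).index(0)
    return est.predict_proba(X)[:, col]


def stack_cv_splits(
    dataset: Dataset, cv_folds: int, rng_seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified K-fold train/validation splits.  When the dataset carries
    ``groups`` (oversampled data tying synthetic rows to their base sample),
    a group-aware splitter keeps each group inside a single fold so
    interpolated minority copies cannot leak across the split."""
    n_min = int(np.sum(dataset.y == 0))
    n_maj = int(np.sum(dataset.y == 1))
    if min(n_min, n_maj) < cv_folds:
        raise ValueError(
            f"smallest class has {min(n_min, n_maj)} samples; "
            f"use cv_folds <= that (got {cv_folds})"
        )
    if dataset.groups is not None:
        cv = StratifiedGroupKFold(n_splits=cv_folds, shuffle=True, random_state=rng_seed)
        splits = list(cv.split(dataset.X, dataset.y, dataset.groups))
    else:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rng_seed)
        splits = list(cv.split(dataset.X, dataset.y))
    for tr, te in splits:
        if len(np.unique(dataset.y[tr])) < 2 or len(np.unique(dataset.y[te])) < 2:
            raise ValueError(
                "a CV fold contains a single class; use fewer folds"
            )
    return splits


def oof_matrix(
    dataset: Dataset,
    pool: ClassifierPool,
    member_indices: np.ndarray,
    cv_folds: int,
    rng_seed: int,
    splits: list | None = None,
) -> np.ndarray:
    """Out-of-fold minority-class probability columns, one per requested
    pool member, over the whole training set (stratified K-fold)."""
    if splits is None:
        splits = stack_cv_splits(dataset, cv_folds, rng_seed)
    Z = np.zeros((dataset.n_samples, len(member_indices)))
    for col, mi in enumerate(member_indices):
        for tr, te in splits:
            est = pool.members[mi].build(rng_seed)
            est.fit(dataset.X[tr], dataset.y[tr])
            Z[te, col] = _minority_proba(est, dataset.X[te])
    return Z


def _meta_learner() -> LogisticRegression:
    # L2 regularization guards the meta-fit against over/underfitting
    return LogisticRegression(C=1.0, max_iter=1000)


@dataclass
class StackModel:
    """A fitted two-layer stack: selected first-layer members plus the
    logistic meta-learner over their probability columns."""

    chromosome: Chromosome
    member_names: list[str]
    first_layer: list
    meta: LogisticRegression
    feature_names: list[str]
    cv_folds: int
    oof_matrix: np.ndarray | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns "
                f"({self.feature_names}), got shape {X.shape}"
            )
        Z = np.column_stack([_minority_proba(est, X) for est in self.first_layer])
        # meta target encodes the minority class as 1
        return self.meta.predict_proba(Z)[:, list(self.meta.classes_).index(1)]


def fit_stack(
    dataset: Dataset,
    chromosome: Chromosome,
    pool: ClassifierPool,
    cv_folds: int = 5,
    rng_seed: int = 0,
) -> StackModel:
    """Fit the two-layer stack for one chromosome.

    Out-of-fold probability columns of the selected members form the
    meta-learner's design matrix; the members are then refit on the full
    training data for deployment.
    """
    if chromosome.n_selected == 0:
        raise ValueError("chromosome selects no classifiers")
    sel = chromosome.selected_indices()
    Z = oof_matrix(dataset, pool, sel, cv_folds, rng_seed)  # group-aware if groups set
    meta = _meta_learner()
    # meta target: 1 for the minority class, matching the probability columns
    meta.fit(Z, (dataset.y == 0).astype(int))
    first_layer = []
    for mi in sel:
        est = pool.members[mi].build(rng_seed)
        est.fit(dataset.X, dataset.y)
        first_layer.append(est)
    return StackModel(
        chromosome=chromosome,
        member_names=[pool.members[mi].name for mi in sel],
        first_layer=first_layer,
        meta=meta,
        feature_names=list(dataset.feature_names),
        cv_folds=cv_folds,
        oof_matrix=Z,
    )


def predict(stack_model: StackModel, X: np.ndarray) -> np.ndarray:
    """Minority-class probability vector for new samples."""
    return stack_model.predict_proba(X)


# ---------------------------------------------------------------------------
# GA operators


def roulette_select(population, fitness_values, n_select, rng) -> list[Chromosome]:
    """Fitness-proportional sampling with replacement: P_i = fit_i / Σ fit_j.

    All-zero fitness degrades to uniform selection with a warning.
    """
    fitness_values = np.asarray(fitness_values, dtype=float)
    if np.any(fitness_values < 0):
        raise ValueError("fitness values must be >= 0")
    total = fitness_values.sum()
    if total == 0:
        warnings.warn("all fitness values are zero; selecting uniformly", stacklevel=2)
        probs = np.full(len(population), 1.0 / len(population))
    else:
        probs = fitness_values / total
    cumulative = np.cumsum(probs)
    picks = np.searchsorted(cumulative, rng.uniform(0, 1, size=n_select), side="left")
    picks = np.minimum(picks, len(population) - 1)
    return [Chromosome(population[int(i)].bits.copy()) for i in picks]


def multipoint_crossover(
    parent_a: Chromosome, parent_b: Chromosome, crossover_points, rng
) -> tuple[Chromosome, Chromosome]:
    """Exchange alternating gene blocks between two parents.

    ``crossover_points`` is either an integer count (that many distinct cut
    positions are drawn uniformly from 1..9) or an explicit iterable of cut
    positions.  Bits at each position are conserved across the two children.
    """
    if np.isscalar(crossover_points):
        k = int(crossover_points)
        if k >= CHROMOSOME_LENGTH:
            raise ValueError("number of crossover points must be < chromosome length")
        cuts = sorted(rng.choice(np.arange(1, CHROMOSOME_LENGTH), size=k, replace=False))
    else:
        cuts = sorted(int(c) for c in crossover_points)
        if any(not 1 <= c <= CHROMOSOME_LENGTH - 1 for c in cuts):
            raise ValueError("cut positions must lie in 1..9")
        if len(set(cuts)) != len(cuts):
            raise ValueError("cut positions must be distinct")
    a = parent_a.bits.copy()
    b = parent_b.bits.copy()
    swap = False
    bounds = [0, *cuts, CHROMOSOME_LENGTH]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if swap:
            a[lo:hi], b[lo:hi] = b[lo:hi].copy(), a[lo:hi].copy()
        swap = not swap
    return Chromosome(a), Chromosome(b)


def multipoint_mutation(chromosome: Chromosome, mutation_rate: float, rng) -> Chromosome:
    """Flip each bit independently with probability ``mutation_rate``; an
    all-zero result is repaired by setting one uniformly random bit."""
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation_rate must be in [0, 1]")
    flips = rng.uniform(0, 1, size=CHROMOSOME_LENGTH) < mutation_rate
    bits = np.where(flips, 1 - chromosome.bits, chromosome.bits)
    if bits.sum() == 0:
        bits = bits.copy()
        bits[rng.integers(0, CHROMOSOME_LENGTH)] = 1
    return Chromosome(bits)


def _repair(bits: np.ndarray, rng) -> np.ndarray:
    if bits.sum() == 0:
        bits = bits.copy()
        bits[rng.integers(0, CHROMOSOME_LENGTH)] = 1
    return bits


# ---------------------------------------------------------------------------
# fitness and search


class StackFitness:
    """Chromosome fitness = nested-CV AUC (or accuracy) of the stacked model.

    For each outer fold, an inner out-of-fold probability matrix is built on
    the outer-train rows only; the logistic meta-learner is fit there, the
    first-layer members are refit on the outer-train and score the untouched
    outer-test — exactly the deployment procedure of :func:`fit_stack`, so
    the fitness estimates generalization without any leakage (a first-layer
    model never sees the rows it is evaluated on).

    All member fits happen once at construction and are shared by every
    chromosome: a chromosome evaluation reduces to one small logistic fit
    per outer fold, which makes both the GA and exhaustive enumeration over
    all 1,023 subsets cheap.  Evaluations are cached by bitstring.
    """

    def __init__(
        self,
        dataset: Dataset,
        pool: ClassifierPool,
        cv_folds: int = 5,
        rng_seed: int = 0,
        metric: str = "auc",
    ):
        self.dataset = dataset
        self.pool = pool
        self.cv_folds = cv_folds
        self.rng_seed = rng_seed
        self.metric = metric
        self.splits = stack_cv_splits(dataset, cv_folds, rng_seed)
        self.target = (dataset.y == 0).astype(int)
        all_members = np.arange(CHROMOSOME_LENGTH)
        self.folds = []
        for tr, te in self.splits:
            sub = Dataset(
                dataset.X[tr],
                dataset.y[tr],
                list(dataset.feature_names),
                None if dataset.provenance is None else dataset.provenance[tr],
                None if dataset.groups is None else dataset.groups[tr],
            )
            inner_k = min(cv_folds, int(np.bincount(sub.y, minlength=2).min()))
            Z_tr = oof_matrix(sub, pool, all_members, inner_k, rng_seed)
            P_te = np.zeros((len(te), CHROMOSOME_LENGTH))
            for mi in all_members:
                est = pool.members[mi].build(rng_seed)
                est.fit(sub.X, sub.y)
                P_te[:, mi] = _minority_proba(est, dataset.X[te])
            self.folds.append(
                {"Z_tr": Z_tr, "y_tr": self.target[tr], "P_te": P_te, "y_te": self.target[te]}
            )
        self._cache: dict[tuple[int, ...], float] = {}

    def member_cv_scores(self) -> np.ndarray:
        """Per-member mean outer-fold AUC (the single-classifier reference)."""
        return np.array(
            [
                np.mean(
                    [roc_auc_score(f["y_te"], f["P_te"][:, mi]) for f in self.folds]
                )
                for mi in range(CHROMOSOME_LENGTH)
            ]
        )

    def __call__(self, chromosome: Chromosome) -> float:
        key = chromosome.key()
        if key not in self._cache:
            self._cache[key] = self._evaluate(chromosome)
        return self._cache[key]

    def _evaluate(self, chromosome: Chromosome) -> float:
        if chromosome.n_selected == 0:
            return 0.0
        sel = chromosome.selected_indices()
        vals = []
        for fold in self.folds:
            meta = _meta_learner()
            meta.fit(fold["Z_tr"][:, sel], fold["y_tr"])
            p = meta.predict_proba(fold["P_te"][:, sel])[
                :, list(meta.classes_).index(1)
            ]
            if self.metric == "auc":
                vals.append(roc_auc_score(fold["y_te"], p))
            else:
                vals.append(np.mean((p >= 0.5).astype(int) == fold["y_te"]))
        return float(np.mean(vals))


def ga_optimize(
    dataset: Dataset,
    pool: ClassifierPool,
    ga_config: GAConfig,
    cv_folds: int = 5,
    fitness: StackFitness | None = None,
) -> tuple[Chromosome, dict]:
    """Search the classifier-subset space with a genetic algorithm.

    Loop per generation: evaluate fitness (CV AUC of the stacked model) →
    carry the single best individual over unchanged (elitism) → roulette
    selection → multipoint crossover at ``crossover_rate`` → per-bit
    mutation.  Returns the best-ever chromosome and a history dict with
    per-generation best / mean fitness and the monotone best-ever trace.
    """
    rng = np.random.default_rng(ga_config.rng_seed)
    if fitness is None:
        fitness = StackFitness(
            dataset, pool, cv_folds, ga_config.rng_seed, ga_config.fitness_metric
        )

    population = [
        Chromosome(_repair(rng.integers(0, 2, size=CHROMOSOME_LENGTH), rng))
        for _ in range(ga_config.population_size)
    ]
    history = {"best": [], "mean": [], "best_ever": []}
    best_chrom: Chromosome | None = None
    best_fit = -np.inf

    for _generation in range(max(ga_config.generations, 1)):
        fits = np.array([fitness(c) for c in population])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_chrom = Chromosome(population[gen_best].bits.copy())
        history["best"].append(float(fits[gen_best]))
        history["mean"].append(float(fits.mean()))
        history["best_ever"].append(best_fit)
        if _generation == max(ga_config.generations, 1) - 1:
            break

        elite = Chromosome(best_chrom.bits.copy())
        parents = roulette_select(
            population, fits, ga_config.population_size - 1, rng
        )
        children: list[Chromosome] = []
        for i in range(0, len(parents) - 1, 2):
            if rng.uniform() < ga_config.crossover_rate:
                c1, c2 = multipoint_crossover(
                    parents[i], parents[i + 1], ga_config.crossover_points, rng
                )
            else:
                c1, c2 = parents[i], parents[i + 1]
            children.extend([c1, c2])
        if len(parents) % 2 == 1:
            children.append(parents[-1])
        children = [
            multipoint_mutation(c, ga_config.mutation_rate, rng) for c in children
        ]
        population = [elite, *children]

    history["n_evaluated"] = len(fitness._cache)
    return best_chrom, history


def exhaustive_search(
    dataset: Dataset,
    pool: ClassifierPool,
    cv_folds: int = 5,
    rng_seed: int = 0,
    metric: str = "auc",
    fitness: StackFitness | None = None,
) -> tuple[Chromosome, float]:
    """Enumerate all 2¹⁰-1 non-empty chromosomes and return the fittest
    (ties → first in enumeration order).  Used as the oracle the GA is
    checked against."""
    if fitness is None:
        fitness = StackFitness(dataset, pool, cv_folds, rng_seed, metric)
    best_bits, best_val = None, -np.inf
    for combo in itertools.product((0, 1), repeat=CHROMOSOME_LENGTH):
        if sum(combo) == 0:
            continue
        val = fitness(Chromosome(np.array(combo)))
        if val > best_val:
            best_val, best_bits = val, np.array(combo)
    return Chromosome(best_bits), float(best_val)


# ---------------------------------------------------------------------------
# grid search


def grid_search(
    classifier_spec: ClassifierSpec,
    dataset: Dataset,
    param_grid: dict | None = None,
    cv_folds: int = 5,
    criterion: str = "auc",
    rng_seed: int = 0,
) -> dict:
    """Enumerate the full Cartesian hyperparameter grid and return the
    combination maximizing stratified-CV ``criterion`` (ties → first in
    enumeration order).

    Returns {"params", "score", "n_combinations"}.
    """
    grid = param_grid if param_grid is not None else classifier_spec.param_grid
    if not grid:
        raise ValueError("empty hyperparameter grid")
    names = list(grid)
    combos = list(itertools.product(*(grid[n] for n in names)))
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rng_seed)
    best_params, best_score = None, -np.inf
    for combo in combos:
        params = dict(zip(names, combo))
        vals = []
        for tr, te in skf.split(dataset.X, dataset.y):
            est = classifier_spec.build(rng_seed, **params)
            est.fit(dataset.X[tr], dataset.y[tr])
            p = _minority_proba(est, dataset.X[te])
            if criterion == "auc":
                vals.append(roc_auc_score(dataset.y[te] == 0, p))
            elif criterion == "accuracy":
                vals.append(np.mean((p >= 0.5) == (dataset.y[te] == 0)))
            else:
                raise ValueError("criterion must be 'auc' or 'accuracy'")
        score = float(np.mean(vals))
        if score > best_score:
            best_score, best_params = score, params
    return {
        "params": best_params,
        "score": best_score,
        "n_combinations": len(combos),
    }
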