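"""F-score filter feature selection and the wrapper loop over subset sizes.

The standard F-score of feature i is a Fisher-style discriminability ratio:
the squared deviations of the two class means from the overall mean, over
the sum of the two within-class sample variances.  The imbalance-aware
("improved") variant keeps only the majority-class variance in the
denominator: when the minority class is tiny its sample variance is an
unstable estimate, and dropping that term favors features that separate the
rare class from the bulk of the data.

Convention (fixed package-wide): label 1 is the majority / "positive-count"
class n+, label 0 is the minority n-.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from imbga.core_data import Dataset


@dataclass
class FeatureScore:
    feature_name: str
    f_standard: float
    f_improved: float
    rank: int


@dataclass
class WrapperResult:
    """Outcome of the incremental-subset wrapper.

    auc_by_dimension maps subset size k to mean CV AUC of the classifier on
    the top-k ranked features; baseline_auc_no_fs is the same classifier on
    all features.
    """

    auc_by_dimension: dict[int, float]
    best_dimension: int
    selected_features: list[str]
    baseline_auc_no_fs: float
    scores: list[FeatureScore] = field(default_factory=list)


def _class_split(dataset: Dataset, feature_index: int) -> tuple[np.ndarray, np.ndarray]:
    col = dataset.X[:, feature_index]
    pos = col[dataset.y == 1]  # majority, n+
    neg = col[dataset.y == 0]  # minority, n-
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"both classes need >= 2 samples (got n+={len(pos)}, n-={len(neg)}); "
            "the variance denominators use n-1"
        )
    return pos, neg


def _fscore_numerator(pos: np.ndarray, neg: np.ndarray) -> float:
    overall = np.mean(np.concatenate([pos, neg]))
    return (pos.mean() - overall) ** 2 + (neg.mean() - overall) ** 2


def fscore_standard(dataset: Dataset, feature_index: int) -> float:
    """Standard F-score: numerator over the sum of both within-class
    variances (each with an n-1 denominator).

    Returns ``inf`` with a warning when the feature is constant inside both
    classes (zero denominator); such features are perfectly degenerate and
    rank above all finite scores.
    """
    pos, neg = _class_split(dataset, feature_index)
    denom = pos.var(ddof=1) + neg.var(ddof=1)
    num = _fscore_numerator(pos, neg)
    if denom == 0:
        warnings.warn(
            f"feature {dataset.feature_names[feature_index]!r} has zero within-class "
            "variance; score flagged as +inf",
            stacklevel=2,
        )
        return float("inf")
    return num / denom


def fscore_improved(dataset: Dataset, feature_index: int) -> float:
    """Imbalance-aware F-score: same numerator, but the denominator keeps
    only the majority-class (label 1) variance."""
    pos, neg = _class_split(dataset, feature_index)
    denom = pos.var(ddof=1)
    num = _fscore_numerator(pos, neg)
    if denom == 0:
        warnings.warn(
            f"feature {dataset.feature_names[feature_index]!r} is constant in the "
            "majority class; score flagged as +inf",
            stacklevel=2,
        )
        return float("inf")
    return num / denom


def rank_features(dataset: Dataset, variant: str = "improved") -> list[FeatureScore]:
    """Score every feature and assign ranks 1..n_features, descending by the
    chosen variant; ties (and +inf degenerates among themselves) break by
    original column order."""
    if variant not in ("standard", "improved"):
        raise ValueError(f"variant must be 'standard' or 'improved', got {variant!r}")
    std = np.array([fscore_standard(dataset, i) for i in range(dataset.n_features)])
    imp = np.array([fscore_improved(dataset, i) for i in range(dataset.n_features)])
    key = imp if variant == "improved" else std
    order = np.argsort(-key, kind="stable")  # stable: ties keep column order
    scores = [
        FeatureScore(dataset.feature_names[i], float(std[i]), float(imp[i]), 0)
        for i in range(dataset.n_features)
    ]
    for rank, i in enumerate(order, start=1):
        scores[i].rank = rank
    return sorted(scores, key=lambda s: s.rank)


def make_classifier(spec, rng_seed: int = 0):
    """Resolve a classifier spec: an estimator instance (cloned) or one of
    the named wrapper learners 'adaboost', 'bagging', 'logistic'."""
    if hasattr(spec, "fit"):
        est = clone(spec)
        if "random_state" in est.get_params():
            est.set_params(random_state=rng_seed)
        return est
    factories = {
        "adaboost": lambda: AdaBoostClassifier(n_estimators=40, random_state=rng_seed),
        "bagging": lambda: BaggingClassifier(n_estimators=25, random_state=rng_seed),
        "logistic": lambda: LogisticRegression(max_iter=1000),
    }
    if spec not in factories:
        raise ValueError(f"unknown classifier spec {spec!r}; known: {sorted(factories)}")
    return factories[spec]()


def _cv_auc_on_columns(
    X: np.ndarray,
    y: np.ndarray,
    columns: np.ndarray,
    spec,
    cv_folds: int,
    rng_seed: int,
    rank_per_fold: bool,
    variant: str,
    names: list[str],
    k: int | None,
) -> float:
    """Mean CV AUC (minority class 0 scored positive).  When rank_per_fold,
    the top-k ranking is recomputed on each training fold to avoid selection
    leakage."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rng_seed)
    aucs = []
    for tr, te in skf.split(X, y):
        if rank_per_fold and k is not None:
            fold_scores = rank_features(Dataset(X[tr], y[tr], list(names)), variant)
            top = [s.feature_name for s in fold_scores[:k]]
            cols = np.array([names.index(n) for n in top])
        else:
            cols = columns
        est = make_classifier(spec, rng_seed)
        est.fit(X[tr][:, cols], y[tr])
        class0 = list(est.classes_).index(0)
        score0 = est.predict_proba(X[te][:, cols])[:, class0]
        aucs.append(roc_auc_score(y[te] == 0, score0))
    return float(np.mean(aucs))


def wrapper_select(
    dataset: Dataset,
    classifier_spec="adaboost",
    max_dim: int | None = None,
    cv_folds: int = 5,
    rng_seed: int = 0,
    variant: str = "improved",
    leaky_single_pass: bool = False,
) -> WrapperResult:
    """Pick the best feature-subset size by incremental evaluation.

    Features are ranked by the chosen F-score variant; for each k in
    1..max_dim the classifier is evaluated by stratified CV AUC on the top-k
    features, and the k maximizing AUC wins (ties -> smallest k, parsimony).
    The all-features baseline AUC is recorded for comparison.

    By default the ranking is recomputed inside each training fold so the
    reported AUCs carry no selection leakage; ``leaky_single_pass=True``
    ranks once on the full data instead (the simpler filter-then-evaluate
    flow).
    """
    if max_dim is None:
        max_dim = dataset.n_features
    if max_dim > dataset.n_features:
        raise ValueError(f"max_dim {max_dim} exceeds {dataset.n_features} features")
    n_min = int(np.sum(dataset.y == 0))
    if cv_folds > n_min:
        raise ValueError(f"cv_folds {cv_folds} exceeds minority count {n_min}")

    names = list(dataset.feature_names)
    scores = rank_features(dataset, variant)
    ranked_cols = np.array([names.index(s.feature_name) for s in scores])

    auc_by_dim: dict[int, float] = {}
    for k in range(1, max_dim + 1):
        auc_by_dim[k] = _cv_auc_on_columns(
            dataset.X,
            dataset.y,
            ranked_cols[:k],
            classifier_spec,
            cv_folds,
            rng_seed,
            rank_per_fold=not leaky_single_pass,
            variant=variant,
            names=names,
            k=k,
        )
    baseline = _cv_auc_on_columns(
        dataset.X,
        dataset.y,
        np.arange(dataset.n_features),
        classifier_spec,
        cv_folds,
        rng_seed,
        rank_per_fold=False,
        variant=variant,
        names=names,
        k=None,
    )
    best_k = min(
        auc_by_dim, key=lambda k: (-auc_by_dim[k], k)
    )  # ties -> smallest dimension
    selected = [s.feature_name for s in scores[:best_k]]
    return WrapperResult(auc_by_dim, best_k, selected, baseline, scores)
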