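"""Hybrid resampling: interpolation-based minority oversampling (AMOM)
followed by iterative Tomek-link cleaning (DUMS).

The oversampler draws each synthetic minority point on the segment between a
minority sample and one of its m nearest minority neighbors, as in SMOTE.
Oversampling near the class boundary creates ambiguous points, so the
cleaning stage then removes, iteratively until a fixed point, the
majority-class member of every cross-class mutual-nearest-neighbor pair
(Tomek link).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from imbga.core_data import (
    PROVENANCE_ORIGINAL,
    PROVENANCE_SYNTHETIC,
    Dataset,
    DegenerateClassError,
    minmax_normalize,
)


@dataclass
class AmomConfig:
    """Oversampler settings.

    m : number of nearest minority neighbors searched per base sample
        (default 5).
    target_ratio : desired minority/majority count ratio after oversampling,
        in (0, 1]; 1.0 means full balance.
    rng_seed : seed for the neighbor choice and the interpolation scalar s.
    """

    m: int = 5
    target_ratio: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not 0 < self.target_ratio <= 1:
            raise ValueError(f"target_ratio must be in (0, 1], got {self.target_ratio}")


@dataclass
class SamplingResult:
    """Dataset after a resampling stage plus provenance.

    synthetic_mask marks rows created by oversampling; deleted_indices are
    row indices of the INPUT dataset removed by cleaning; iterations counts
    cleaning passes (1 for a pure oversampling result).
    """

    dataset: Dataset
    synthetic_mask: np.ndarray
    deleted_indices: list[int] = field(default_factory=list)
    iterations: int = 1


def _nearest_neighbor_indices(X: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Index of each row's nearest other row (Euclidean); ties broken by
    lowest row index."""
    n = X.shape[0]
    nn = np.empty(n, dtype=int)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(X[start:stop], X)
        for i in range(stop - start):
            d[i, start + i] = np.inf
        nn[start:stop] = np.argmin(d, axis=1)
    return nn


def tomek_links(X: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    """All cross-class mutual-nearest-neighbor pairs (i, j), i < j."""
    nn = _nearest_neighbor_indices(X)
    links = []
    for i in range(len(y)):
        j = nn[i]
        if j > i and nn[j] == i and y[i] != y[j]:
            links.append((i, int(j)))
    return links


def amom_oversample(dataset: Dataset, config: AmomConfig) -> SamplingResult:
    """Oversample the minority class by segment interpolation.

    Each synthetic sample is ``u_i + s * (u_ij - u_i)`` where ``u_ij`` is one
    of ``u_i``'s m nearest minority neighbors (Euclidean distance on
    min-max-normalized features) and ``s ~ Uniform(0, 1)``.  New samples are
    appended until the minority count reaches
    ``ceil(target_ratio * majority_count)``.  Deterministic under
    ``config.rng_seed``.
    """
    n_min, n_maj = dataset.class_counts()
    if n_min == 0 or n_maj == 0:
        raise DegenerateClassError("oversampling needs both classes non-empty")
    if n_min < config.m + 1:
        raise ValueError(
            f"minority class has {n_min} samples but m={config.m} neighbors were "
            f"requested; use m <= {n_min - 1}"
        )
    target = int(np.ceil(config.target_ratio * n_maj))
    if target < n_min:
        raise ValueError(
            f"target_ratio {config.target_ratio} would shrink the minority class "
            f"({n_min} -> {target}); oversampling only adds samples"
        )
    rng = np.random.default_rng(config.rng_seed)
    min_idx = np.nonzero(dataset.y == 0)[0]
    X_min = dataset.X[min_idx]

    # neighbor search in normalized space so no single feature dominates
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm, _ = minmax_normalize(dataset)
    Xn_min = norm.X[min_idx]
    d = cdist(Xn_min, Xn_min)
    np.fill_diagonal(d, np.inf)
    # m nearest minority neighbors per minority sample, stable order
    neighbor_idx = np.argsort(d, axis=1, kind="stable")[:, : config.m]

    n_new = target - n_min
    new_rows = np.empty((n_new, dataset.n_features))
    bases = rng.integers(0, n_min, size=n_new)
    picks = rng.integers(0, config.m, size=n_new)
    s = rng.uniform(0.0, 1.0, size=n_new)
    for k in range(n_new):
        ui = X_min[bases[k]]
        uij = X_min[neighbor_idx[bases[k], picks[k]]]
        new_rows[k] = ui + s[k] * (uij - ui)

    X_out = np.vstack([dataset.X, new_rows])
    y_out = np.concatenate([dataset.y, np.zeros(n_new, dtype=int)])
    prov_in = (
        dataset.provenance
        if dataset.provenance is not None
        else np.array([PROVENANCE_ORIGINAL] * dataset.n_samples, dtype=object)
    )
    prov = np.concatenate([prov_in, np.array([PROVENANCE_SYNTHETIC] * n_new, dtype=object)])
    # each synthetic row joins the CV group of its base sample so
    # interpolation copies never straddle a train/validation split
    groups_in = (
        dataset.groups if dataset.groups is not None else np.arange(dataset.n_samples)
    )
    groups = np.concatenate([groups_in, groups_in[min_idx[bases]]])
    out = Dataset(X_out, y_out, list(dataset.feature_names), prov, groups)
    mask = np.zeros(out.n_samples, dtype=bool)
    mask[dataset.n_samples :] = True
    return SamplingResult(out, mask, [], 1)


def dums_clean(dataset: Dataset, policy: str = "majority") -> SamplingResult:
    """Iteratively remove Tomek-link members until no cross-class
    mutual-nearest-neighbor pair remains.

    ``policy`` is ``"majority"`` (delete the majority member of each link;
    default, preserves scarce minority information) or ``"both"``.  If a
    deletion pass would empty a class, cleaning stops with a warning.
    Deterministic: distance ties break toward the lowest row index.
    """
    if policy not in ("majority", "both"):
        raise ValueError(f"policy must be 'majority' or 'both', got {policy!r}")
    n_min, n_maj = dataset.class_counts()
    if n_min == 0 or n_maj == 0:
        raise DegenerateClassError("cleaning needs both classes non-empty")
    if dataset.n_samples > 1 and np.all(dataset.X == dataset.X[0]):
        raise ValueError("all samples identical: nearest-neighbor pairs are ill-defined")

    keep = np.arange(dataset.n_samples)
    X, y = dataset.X, dataset.y
    deleted: list[int] = []
    iterations = 0
    while True:
        iterations += 1
        links = tomek_links(X[keep], y[keep])
        if not links:
            break
        drop_local: set[int] = set()
        for i, j in links:
            if policy == "both":
                drop_local.update((i, j))
            else:
                drop_local.add(i if y[keep[i]] == 1 else j)
        survivors_y = np.delete(y[keep], sorted(drop_local))
        if np.sum(survivors_y == 0) == 0 or np.sum(survivors_y == 1) == 0:
            warnings.warn(
                "cleaning stopped: removing remaining links would empty a class",
                stacklevel=2,
            )
            break
        deleted.extend(int(keep[i]) for i in sorted(drop_local))
        keep = np.delete(keep, sorted(drop_local))

    prov = dataset.provenance[keep] if dataset.provenance is not None else None
    grp = dataset.groups[keep] if dataset.groups is not None else None
    out = Dataset(X[keep], y[keep], list(dataset.feature_names), prov, grp)
    mask = np.zeros(out.n_samples, dtype=bool)
    if dataset.provenance is not None:
        mask = np.asarray(prov == PROVENANCE_SYNTHETIC, dtype=bool)
    return SamplingResult(out, mask, sorted(deleted), iterations)


def amom_dums(
    dataset: Dataset, config: AmomConfig, policy: str = "majority"
) -> SamplingResult:
    """Hybrid resampling: oversample, then clean the union of original and
    synthetic rows.  Both synthetic and original rows are candidates for
    deletion under the cleaning policy."""
    over = amom_oversample(dataset, config)
    cleaned = dums_clean(over.dataset, policy=policy)
    return SamplingResult(
        cleaned.dataset,
        cleaned.synthetic_mask,
        cleaned.deleted_indices,
        cleaned.iterations,
    )
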