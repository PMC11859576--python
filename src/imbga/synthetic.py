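"""Synthetic imbalanced tabular data with controllable structure.

Generates two-class Gaussian-cluster datasets shaped like small clinical
cohorts: a rare outcome class (label 0), a large control class (label 1), a
handful of genuinely informative features, correlated nuisance features that
shadow them, and pure-noise features.  Class separation is parameterized in
pooled-standard-deviation units (the Euclidean distance between the class
mean vectors in the informative subspace), so discriminability has a
closed-form expectation: for separation d, the Bayes AUC is Φ(d/√2).

Presets mirror the class-count shapes of published hospital cohorts for
hyperbilirubinemia (392/1,695), preeclampsia (86/2,008), preterm birth
(122/1,958) and a 25-feature pregnancy-hypertension screening cohort
(42/2,136, unbalanced ratio ≈ 50.86).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from imbga.core_data import Dataset


@dataclass
class ScenarioConfig:
    """Generator settings.

    class_separation is the distance between class means in the informative
    subspace, in pooled-SD units (features have unit variance).
    redundancy_rho is the target correlation of each redundant feature with
    its informative parent.  label_noise flips each label independently with
    that probability.  derived_ratio_feature appends a biomarker-ratio-style
    feature f_a / f_b built from the first two informative features (with the
    denominator location-shifted away from zero).
    """

    n_majority: int = 1000
    n_minority: int = 100
    n_informative: int = 5
    n_redundant: int = 5
    n_noise: int = 10
    class_separation: float = 1.5
    redundancy_rho: float = 0.7
    label_noise: float = 0.0
    rng_seed: int = 0
    derived_ratio_feature: bool = False

    def __post_init__(self) -> None:
        if min(self.n_majority, self.n_minority) < 1:
            raise ValueError("both class counts must be >= 1")
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if min(self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be >= 0")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if not 0 <= self.redundancy_rho < 1:
            raise ValueError("redundancy_rho must be in [0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")

    @property
    def n_features(self) -> int:
        return (
            self.n_informative
            + self.n_redundant
            + self.n_noise
            + (1 if self.derived_ratio_feature else 0)
        )

    def to_dict(self) -> dict:
        return asdict(self)


def generate(config: ScenarioConfig) -> Dataset:
    """Draw a dataset from the scenario.  Deterministic under rng_seed."""
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_majority + config.n_minority
    y = np.concatenate(
        [np.zeros(config.n_minority, dtype=int), np.ones(config.n_majority, dtype=int)]
    )

    # informative block: unit-variance Gaussians, class means offset so the
    # Euclidean distance between mean vectors equals class_separation
    offset = config.class_separation / np.sqrt(config.n_informative)
    informative = rng.standard_normal((n, config.n_informative))
    informative[y == 0] += offset  # minority shifted up along every informative axis

    blocks = [informative]
    names = [f"informative_{i}" for i in range(config.n_informative)]

    if config.n_redundant:
        rho = config.redundancy_rho
        parents = np.array(
            [i % config.n_informative for i in range(config.n_redundant)]
        )
        noise = rng.standard_normal((n, config.n_redundant))
        redundant = rho * informative[:, parents] + np.sqrt(1 - rho**2) * noise
        blocks.append(redundant)
        names += [
            f"redundant_{i}_of_informative_{parents[i]}"
            for i in range(config.n_redundant)
        ]

    if config.n_noise:
        blocks.append(rng.standard_normal((n, config.n_noise)))
        names += [f"noise_{i}" for i in range(config.n_noise)]

    if config.derived_ratio_feature:
        num = informative[:, 0]
        den_src = informative[:, 1] if config.n_informative > 1 else informative[:, 0]
        den = den_src + 5.0  # location shift keeps the denominator away from 0
        blocks.append((num / den)[:, None])
        names.append("ratio_informative_0_over_1")

    X = np.hstack(blocks)

    if config.label_noise > 0:
        flips = rng.uniform(0, 1, size=n) < config.label_noise
        y = np.where(flips, 1 - y, y)
        if len(np.unique(y)) < 2:
            raise ValueError("label noise emptied a class; lower label_noise")

    # shuffle rows so class blocks are not contiguous
    perm = rng.permutation(n)
    return Dataset(X[perm], y[perm], names)


_PRESETS = {
    # (minority, majority, informative, redundant, noise)
    "tableA": dict(n_minority=392, n_majority=1695, n_informative=4, n_redundant=3, n_noise=3),
    "tableB": dict(n_minority=86, n_majority=2008, n_informative=4, n_redundant=3, n_noise=3),
    "tableC": dict(n_minority=122, n_majority=1958, n_informative=4, n_redundant=3, n_noise=3),
    # 25-feature screening cohort, UR ≈ 50.86
    "pih1": dict(n_minority=42, n_majority=2136, n_informative=5, n_redundant=8, n_noise=12),
}


def preset(name: str, rng_seed: int = 0) -> ScenarioConfig:
    """Named scenario matching a published cohort shape.

    Known presets: tableA (392/1,695), tableB (86/2,008), tableC
    (122/1,958), pih1 (42/2,136 with 25 features).
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    return ScenarioConfig(rng_seed=rng_seed, **_PRESETS[name])
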