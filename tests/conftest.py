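import numpy as np
import pytest

from imbga.core_data import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def six_sample_dataset():
    """Minority (label 0) values [0, 0, 1]; majority (label 1) values [2, 3, 4]."""
    X = np.array([[0.0], [0.0], [1.0], [2.0], [3.0], [4.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    return Dataset(X, y, ["marker"])


@pytest.fixture
def separated_clusters():
    """Two tight, well-separated clusters: no cross-class Tomek links."""
    rng = np.random.default_rng(7)
    X0 = rng.normal(0.0, 0.05, size=(20, 2))
    X1 = rng.normal(5.0, 0.05, size=(60, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * 20 + [1] * 60)
    return Dataset(X, y)


def make_imbalanced(n_min=30, n_maj=120, sep=1.5, n_features=4, seed=0):
    """Gaussian two-class fixture without going through the generator module."""
    rng = np.random.default_rng(seed)
    X0 = rng.standard_normal((n_min, n_features)) + sep / np.sqrt(n_features)
    X1 = rng.standard_normal((n_maj, n_features))
    X = np.vstack([X0, X1])
    y = np.array([0] * n_min + [1] * n_maj)
    perm = rng.permutation(len(y))
    return Dataset(X[perm], y[perm])
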