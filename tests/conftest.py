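import numpy as np
import pytest

from idadx import LabeledDataset, SimConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_ds(X, y, names=None, name="fixture"):
    X = np.asarray(X, dtype=float)
    if names is None:
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    return LabeledDataset(X, tuple(names), np.asarray(y, dtype=bool), name=name)


@pytest.fixture
def imbalanced_ds(rng):
    """25 majority (True) vs 10 minority (False), mildly separated."""
    Xmaj = rng.normal(0.0, 1.0, size=(25, 3))
    Xmin = rng.normal(2.0, 1.0, size=(10, 3))
    X = np.vstack([Xmaj, Xmin])
    y = np.array([True] * 25 + [False] * 10)
    return make_ds(X, y)


def two_gaussians(seed, n=200, ratio=1.5):
    """Well-separated two-class Gaussian fixture (for noise-filter checks)."""
    cfg = SimConfig(n=n, p=4, class_ratio=ratio,
                    class_shift={"X1": 4.0, "X2": 3.0}, seed=seed)
    return generate(cfg)
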