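import numpy as np
import pytest

from rifsvm.datasets import LabeledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separated_clusters():
    """Two tight, widely separated clusters: gap far exceeds cluster diameter."""
    rng = np.random.default_rng(7)
    pos = rng.normal(loc=(0.0, 0.0), scale=0.05, size=(20, 2))
    neg = rng.normal(loc=(10.0, 10.0), scale=0.05, size=(60, 2))
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(20, dtype=int), -np.ones(60, dtype=int)])
    return LabeledDataset(X, y, "separated")


def random_imbalanced_dataset(rng, n_pos=None, n_neg=None, d=None):
    """A random two-Gaussian imbalanced dataset for property checks."""
    n_pos = n_pos or int(rng.integers(5, 25))
    n_neg = n_neg or int(rng.integers(n_pos + 1, 80))
    d = d or int(rng.integers(2, 5))
    mu_pos = rng.uniform(-1, 1, d)
    mu_neg = rng.uniform(-1, 1, d)
    X = np.vstack(
        [
            rng.normal(mu_pos, 0.5, size=(n_pos, d)),
            rng.normal(mu_neg, 0.5, size=(n_neg, d)),
        ]
    )
    y = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)])
    perm = rng.permutation(len(y))
    return LabeledDataset(X[perm], y[perm], "random")
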