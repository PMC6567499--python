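import numpy as np
import pytest

from drcomb import ExpressionDataset


@pytest.fixture
def tiny_labeled():
    """Balanced 8-sample, 3-feature dataset with an informative feature 0."""
    rng = np.random.default_rng(42)
    y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    X = rng.standard_normal((8, 3))
    X[:, 0] += 2.0 * y
    return ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(8)],
        feature_ids=["f0", "f1", "f2"],
        values=X,
        labels=y,
    )


@pytest.fixture
def balanced_dataset():
    """20-sample, 5-feature dataset; features 0-1 carry the class signal."""
    rng = np.random.default_rng(7)
    y = np.repeat([0, 1], 10)
    X = rng.standard_normal((20, 5))
    X[:, :2] += 1.5 * y[:, None]
    perm = rng.permutation(20)
    return ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(20)],
        feature_ids=[f"g{j}" for j in range(5)],
        values=X[perm],
        labels=y[perm],
    )
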