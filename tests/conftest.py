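import numpy as np
import pytest

from synrank import CaseControlDataset, SynergyNetwork


def make_noise_dataset(n=100, d=8, seed=0):
    """Features and outcome mutually independent."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = rng.integers(0, 2, size=n)
    while y.min() == y.max():  # pragma: no cover
        y = rng.integers(0, 2, size=n)
    return CaseControlDataset(X, y)


def make_interaction_dataset(n=200, d=6, pair=(1, 3), beta=3.0, seed=0):
    """Pure pairwise interaction, no main effects."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    logit = beta * X[:, pair[0]] * X[:, pair[1]]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    while y.min() == y.max():  # pragma: no cover
        y = rng.integers(0, 2, size=n)
    return CaseControlDataset(X, y)


def random_network(n=8, seed=0, lam=1.0):
    """Random nonnegative synergy network for oracle comparisons."""
    rng = np.random.default_rng(seed)
    node = rng.uniform(0, 3, size=n)
    edge = np.triu(rng.uniform(0, 3, size=(n, n)), k=1)
    edge = edge + edge.T
    return SynergyNetwork(
        node_weights=node,
        edge_weights=edge,
        lam=lam,
        feature_names=[f"v{i + 1}" for i in range(n)],
    )


@pytest.fixture
def noise_dataset():
    return make_noise_dataset(seed=42)


@pytest.fixture
def interaction_dataset():
    return make_interaction_dataset(seed=7)
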