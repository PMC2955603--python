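import numpy as np
import pytest

from tvdbn.model import ExpressionDataset, Hyperparameters


@pytest.fixture
def hyper():
    return Hyperparameters()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """3 genes x 5 time-points x 2 replicates, complete."""
    values = rng.normal(size=(3, 5, 2))
    return ExpressionDataset(gene_ids=["g0", "g1", "g2"], values=values)


@pytest.fixture
def toy_dataset(rng):
    """Target + 2 candidates, n=5, m=1 — small enough for exhaustive enumeration."""
    values = rng.normal(size=(3, 5, 1))
    return ExpressionDataset(gene_ids=["target", "c0", "c1"], values=values)
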