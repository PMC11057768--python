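import numpy as np
import pandas as pd
import pytest

from covar import ExpressionMatrix, InfluenceNetwork


@pytest.fixture
def small_expression():
    """10 samples x 6 genes of positive values, deterministic."""
    rng = np.random.default_rng(123)
    df = pd.DataFrame(
        rng.gamma(shape=2.0, scale=50.0, size=(10, 6)),
        index=[f"s{i}" for i in range(10)],
        columns=[f"g{i}" for i in range(6)],
    )
    return ExpressionMatrix(df, condition="control")


@pytest.fixture
def random_network():
    """5-gene influence network with random column-normalized weights."""
    rng = np.random.default_rng(7)
    N = 5
    W = rng.uniform(size=(N, N))
    np.fill_diagonal(W, 0.0)
    W = W / W.sum(axis=0, keepdims=True)
    return InfluenceNetwork([f"g{i}" for i in range(N)], W, condition="perturbed")


def make_network(W, genes=None, condition="perturbed"):
    W = np.asarray(W, dtype=float)
    genes = genes or [chr(ord("A") + i) for i in range(W.shape[0])]
    return InfluenceNetwork(list(genes), W, condition=condition)
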