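import numpy as np
import pandas as pd
import pytest

from nbstates import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """4 genes x 4 samples, two groups of two."""
    df = pd.DataFrame(
        {
            "A_r1": [10, 20, 5, 100],
            "A_r2": [12, 18, 6, 90],
            "B_r1": [11, 21, 4, 95],
            "B_r2": [9, 19, 7, 105],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    cond = pd.Series(
        ["A", "A", "B", "B"], index=["A_r1", "A_r2", "B_r1", "B_r2"]
    )
    return CountMatrix(df, cond)


def random_count_df(rng, n_genes=50, n_samples=4, mean=50.0):
    values = rng.poisson(mean, size=(n_genes, n_samples))
    return pd.DataFrame(
        values,
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
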