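import numpy as np
import pytest

import serm


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_params():
    """A desk-sized version of the group simulation for fast unit tests."""
    return serm.GroupSimParams(
        n_groups=3, n_cells_per_group=50, n_genes=80, seed=3
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    """Small benchmark: 150 cells x 80 genes, observed at 1% efficiency."""
    return serm.simulate_benchmark(small_params, efficiency=1.0, seed=3)


def random_matrix(rng, q, m, scale=10.0, prefix=""):
    values = rng.gamma(1.0, scale, (q, m))
    return serm.ExpressionMatrix(
        values,
        [f"{prefix}cell_{i}" for i in range(q)],
        [f"{prefix}gene_{j}" for j in range(m)],
    )
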