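import numpy as np
import pytest

import prenetmirt as pm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def A_bench():
    return pm.benchmark_loading_matrix()


@pytest.fixture(scope="session")
def small_responses():
    """A small benchmark-model dataset shared across tests (N=100)."""
    return pm.simulate_responses(pm.benchmark_true_model(100), rng=7)


@pytest.fixture(scope="session")
def tiny_path():
    """A short warm-started prenet path on a small dataset, fitted once."""
    Y = pm.simulate_responses(pm.benchmark_true_model(100), rng=11)
    cfg = pm.StemConfig(n_burnin=40, n_average=20, n_burnin_warm=20, seed=5)
    grid = 3.0 * 0.8 ** np.arange(0, 21, 4)
    return pm.fit_path(Y, 3, "prenet", 0.1, grid, cfg)
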