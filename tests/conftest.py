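import numpy as np
import pytest

from metabobench.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_config():
    """A miniature study configuration for fast end-to-end tests."""
    return SimulationConfig(
        n_blocks=4,
        block_size=5,
        total_samples=60,
        dirichlet_alpha=(4.0, 4.0, 4.0),
        min_per_class=10,
    )


@pytest.fixture(scope="session")
def small_baseline(small_config):
    return simulate_dataset(small_config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def toy_multiclass():
    """Well-separated 3-class data: 30 samples x 8 metabolites."""
    rng = np.random.default_rng(42)
    centers = np.array(
        [[0.0] * 8, [3.0, 3.0, 0, 0, 0, 0, 0, 0], [0, 0, 3.0, 3.0, 0, 0, 0, 0]]
    )
    y = np.repeat([0, 1, 2], 10)
    X = centers[y] + rng.standard_normal((30, 8))
    return X, y
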