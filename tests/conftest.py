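import numpy as np
import pytest

from stacn import simulate


@pytest.fixture(scope="session")
def small_slice():
    """10x10 grid, 2 domains, modest noise — fast shared fixture."""
    spec = simulate.SyntheticSpec(
        grid_shape=(10, 10), n_domains=2, n_genes=60, n_markers_per_domain=8,
        marker_lift=1.2, noise_sd=0.2, dropout_rate=0.1, seed=7,
    )
    return simulate.generate_slice(spec)


@pytest.fixture(scope="session")
def default_slice():
    """The default simulated conditions (20x20 grid, 4 banded domains)."""
    return simulate.generate_slice(simulate.SyntheticSpec(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
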