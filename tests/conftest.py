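import numpy as np
import pytest

from condenstat import SimParams, simulate_cell


@pytest.fixture(scope="session")
def small_cell():
    """One compact noise-free simulated cell used by several tests."""
    params = SimParams(
        seed=5, image_shape=(160, 160), n_aggregates=10, n_condensates=1,
        bg_sd=0.0, light_schedule=[(1, 4)], n_frames=6,
    )
    return simulate_cell(params)


@pytest.fixture(scope="session")
def cycling_cell():
    """One default cycling experiment (3 cycles + final condensation)."""
    return simulate_cell(SimParams(seed=2))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
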