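import numpy as np
import pytest

import gnlcorr as g


@pytest.fixture(scope="session")
def generic_model():
    return g.default_generic_model()


@pytest.fixture(scope="session")
def generic_field(generic_model):
    """Generic tensor on a 10-mm grid over the full 600-mm FOV."""
    return g.evaluate_generic_tensor(generic_model, g.GridSpec.centered(600.0, 10.0))


@pytest.fixture(scope="session")
def coarse_field(generic_model):
    """Cheap 20-mm version for tests that only need plausible structure."""
    return g.evaluate_generic_tensor(generic_model, g.GridSpec.centered(600.0, 20.0))


@pytest.fixture
def small_config():
    """Down-scaled acquisition (64-matrix, 13 slices) for fast simulations."""
    return g.SimulationConfig(
        matrix=64, n_slices=13, slice_spacing_mm=13.0, snr_b1000=None, seed=11
    )


def identity_field(grid=None):
    grid = grid or g.GridSpec.centered(200.0, 50.0)
    t = np.broadcast_to(np.eye(3), grid.shape + (3, 3)).copy()
    return g.NonlinearityTensorField(grid, t)


@pytest.fixture
def identity_tensor():
    return identity_field()
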