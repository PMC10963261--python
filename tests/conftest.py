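import numpy as np
import pytest

from chronolight import default_basis, gaussian_device


@pytest.fixture(scope="session")
def basis():
    return default_basis()


@pytest.fixture(scope="session")
def device():
    """The synthetic five-primary validation device (430-630 nm Gaussians)."""
    return gaussian_device()


@pytest.fixture(scope="session")
def background(device, basis):
    from chronolight import solve_background

    weights, residual = solve_background(device, basis, target_illuminance=93.5)
    return weights, residual


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
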