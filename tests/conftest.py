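import numpy as np
import pytest

from epighost.metrics import object_and_ghost_masks
from epighost.presets import band_phantom, default_phantom, ripple_protocol


@pytest.fixture(scope="session")
def phantom96():
    phantom, raster = default_phantom(96)
    return phantom


@pytest.fixture(scope="session")
def band_phantom96():
    phantom, raster = band_phantom(96)
    return phantom


@pytest.fixture(scope="session")
def masks96(phantom96):
    support = phantom96.support_mask(96)
    return object_and_ghost_masks(support)


@pytest.fixture(scope="session")
def ripple96():
    return ripple_protocol(N=96)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250402)


def ghost_energy(img: np.ndarray, ghost_mask: np.ndarray) -> float:
    return float(np.sum(np.abs(img)[ghost_mask] ** 2))
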