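import numpy as np
import pytest

from foodseg import SpectralCube, make_phantom, preset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_cube(rng):
    """A tiny 8x9x4 cube with distinct, noisy bands."""
    data = rng.uniform(0.1, 0.9, size=(8, 9, 4))
    return SpectralCube(data=data, wavelengths=[400, 500, 600, 700])


@pytest.fixture(scope="session")
def meat_truth():
    """One meat-like phantom shared by the slower end-to-end tests."""
    return make_phantom(preset("meat", shape=(128, 128, 18), seed=7))
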