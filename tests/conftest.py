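import numpy as np
import pytest

from spectralstain.hsi_core import HyperspectralCube, make_wavelength_grid
from spectralstain.synthetic_data import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def grid61():
    return make_wavelength_grid(420, 720, 5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_cube(grid61, rng):
    return HyperspectralCube(rng.uniform(0.0, 1.1, size=(4, 5, 61)), grid61)


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(PhantomConfig(size=(32, 32), seed=7))


@pytest.fixture(scope="session")
def phantom_pool():
    """Small pools of phantom cubes/tiles shared across training tests."""
    he = [
        generate_phantom(PhantomConfig(size=(32, 32), seed=s)).he_cube
        for s in range(4)
    ]
    evg = [
        generate_phantom(PhantomConfig(size=(32, 32), seed=50 + s)).evg_rgb
        for s in range(4)
    ]
    return he, evg
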