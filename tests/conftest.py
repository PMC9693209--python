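import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from fluorostress.hsi_io import HyperspectralCube
from fluorostress.indices import BandLookup
from fluorostress.synthetic import SceneParams, default_wavelengths, make_dataset


@pytest.fixture(scope="session")
def grid128():
    """The instrument grid the defaults emulate: 128 bands, 397-1003 nm."""
    return default_wavelengths()


@pytest.fixture(scope="session")
def lookup128(grid128):
    return BandLookup.build(grid128)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cube(rng, grid128):
    """10 x 10 x 128 random reflectance cube on the default grid."""
    return HyperspectralCube(rng.uniform(0, 1, size=(10, 10, 128)), grid128)


@pytest.fixture(scope="session")
def default_table():
    """The default synthetic feature table: 131 samples, 45/43/43."""
    return make_dataset(SceneParams(seed=0))
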