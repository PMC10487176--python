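import numpy as np
import pytest

from utepi import PhantomSpec
from utepi.synthetic import make_specimen
from utepi.volume import VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20230831)


@pytest.fixture
def small_grid(rng):
    return VoxelGrid(rng.normal(size=(8, 8, 8)), (0.273, 0.273, 0.4))


@pytest.fixture(scope="session")
def half_spec():
    """Geometrically downscaled phantom for fast end-to-end tests."""
    return PhantomSpec.scaled(0.5, seed=11)


@pytest.fixture(scope="session")
def half_specimen(half_spec):
    return make_specimen(half_spec, horse="horse1", limb="LF")
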