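import numpy as np
import pytest

from ulmkit.grids import GridSpec
from ulmkit.psf import make_psf


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture(scope="session")
def small_grid():
    """Quarter-size window for fast rendering in unit tests."""
    return GridSpec(window=40)


@pytest.fixture(scope="session")
def psf():
    """The aspect-ratio-1.81 kernel used across evaluation scenarios."""
    return make_psf(500.0, 276.0, 0.0)


@pytest.fixture(scope="session")
def round_psf():
    return make_psf(400.0, 400.0, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
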