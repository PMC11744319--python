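import numpy as np
import pytest

from stomaspec.fixtures import spectral_library
from stomaspec.retina import default_retina
from stomaspec.spectral import DEFAULT_GRID, Spectrum


@pytest.fixture(scope="session")
def retina():
    return default_retina()


@pytest.fixture(scope="session")
def library():
    return spectral_library()


@pytest.fixture(scope="session")
def daylight(library):
    return library["illuminants"]["natural"]


def flat_spectrum(value, kind, grid=DEFAULT_GRID):
    return Spectrum(grid, np.full(len(grid), float(value)), kind)


@pytest.fixture
def flat():
    return flat_spectrum
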