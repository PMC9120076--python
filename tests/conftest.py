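import numpy as np
import pytest

from rspat.acoustics import RingArrayGeometry, TransducerResponse
from rspat.spectra_kinetics import default_spectra


@pytest.fixture(scope="session")
def lib():
    """Packaged extinction-spectra fixture."""
    return default_spectra()


@pytest.fixture(scope="session")
def small_geom():
    """Reduced ring geometry for fast forward/recon tests."""
    return RingArrayGeometry(n_elements=64, n_samples=560)


@pytest.fixture(scope="session")
def small_grid():
    """(shape, pixel_size_mm) for the reduced 25.6 mm field."""
    return (128, 128), 0.2


@pytest.fixture(scope="session")
def transducer():
    return TransducerResponse()


def point_source(shape, iy, ix, amplitude=1.0):
    p0 = np.zeros(shape)
    p0[iy, ix] = amplitude
    return p0
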