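import numpy as np
import pytest

from demsi.datacube import MSIDataCube
from demsi.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_cube(rng):
    """A small random cube with an irregular tissue mask."""
    X, Y, H = 8, 8, 10
    intens = rng.random((X, Y, H))
    mask = np.ones((X, Y), dtype=bool)
    mask[0, :2] = False
    intens[~mask, :] = 0.0
    mz = 100.0 + np.arange(H) * 5.0
    return MSIDataCube(intensities=intens, mz_axis=mz, pixel_mask=mask, meta={"unit": "au"})


@pytest.fixture(scope="session")
def small_phantom():
    """Default-parameter phantom at 32 px, shared across tests (read-only)."""
    return generate_phantom(PhantomConfig(shape=(32, 32), seed=7))
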