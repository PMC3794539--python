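import numpy as np
import pytest

import srrkit as sk


@pytest.fixture(scope="session")
def small_resolution_volume():
    """5-tube phantom on a 48^3 grid, coarse but fast."""
    spec = sk.PhantomSpec(grid_shape=(48, 48, 48), spacing=(0.2,) * 3, tube_length_mm=6.0)
    return spec, sk.make_resolution_phantom(spec)


@pytest.fixture(scope="session")
def biological_64():
    shape, spacing = (64, 64, 64), (0.1, 0.1, 0.1)
    vol = sk.make_biological_phantom(shape, spacing, seed=0)
    layout = sk.biological_phantom_layout(shape, spacing, seed=0)
    return vol, layout


@pytest.fixture(scope="session")
def smooth_blob_48():
    """Band-limited test volume: an isotropic Gaussian blob."""
    n = 48
    z, y, x = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    c = (n - 1) / 2.0
    data = 100.0 * np.exp(-((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) / (2 * 8.0**2))
    return sk.Volume(data, spacing=(0.2,) * 3)
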