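import numpy as np
import pytest

from ironmap.forward import forward_field, simulate_mgre
from ironmap.geometry import AcquisitionGeometry
from ironmap.phantom import make_phantom


@pytest.fixture(scope="session")
def geometry():
    return AcquisitionGeometry()


@pytest.fixture(scope="session")
def phantom(geometry):
    return make_phantom(geometry, seed=0)


@pytest.fixture(scope="session")
def phantom_field(phantom, geometry):
    return forward_field(phantom, geometry)


@pytest.fixture(scope="session")
def noiseless_series(phantom, phantom_field, geometry):
    return simulate_mgre(phantom, phantom_field, geometry, snr=np.inf, seed=0)


@pytest.fixture(scope="session")
def small_geometry():
    """Coarse grid for spectral identities where full resolution is overkill."""
    return AcquisitionGeometry(grid_shape=(24, 24, 24), voxel_size_mm=(2.0, 2.0, 2.0))
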