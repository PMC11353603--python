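import numpy as np
import pytest

from microtract.io import DWIDataset
from microtract.phantom import make_scheme


@pytest.fixture(scope="session")
def scheme():
    """Study acquisition: b = 0 / 1000 / 2500 s/mm², 64 directions per shell."""
    return make_scheme(64, (1000.0, 2500.0), 1)


@pytest.fixture(scope="session")
def low_b_scheme():
    """Low-b scheme where the quadratic cumulant truncation is negligible."""
    return make_scheme(64, (80.0, 200.0), 1)


def voxel_dataset(signal, shape=(2, 2, 2), s0=1000.0, affine=None):
    """Tile a single normalized voxel signal into a small 4D dataset."""
    vol = np.tile(np.asarray(signal, dtype=float) * s0, shape + (1,))
    return DWIDataset(vol, np.eye(4) if affine is None else affine)


@pytest.fixture(scope="session")
def make_voxel_dataset():
    return voxel_dataset
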