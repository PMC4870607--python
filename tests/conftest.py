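import numpy as np
import pytest

from porepath import PORE, WALL, VoxelGrid, make_random_blob


@pytest.fixture
def all_pore():
    return VoxelGrid(np.zeros((10, 10, 10), np.uint8), 1.0)


@pytest.fixture
def all_wall():
    return VoxelGrid(np.ones((8, 8, 8), np.uint8), 1.0)


@pytest.fixture
def channel_grid():
    """Straight 5-voxel-wide square channel along z, walls elsewhere."""
    data = np.full((30, 13, 13), WALL, np.uint8)
    data[:, 4:9, 4:9] = PORE
    return VoxelGrid(data, 1.0)


def random_grid(seed, shape=(20, 20, 20), porosity=0.6, spacing_um=1.0):
    return make_random_blob(shape, spacing_um=spacing_um, porosity=porosity, seed=seed)


@pytest.fixture
def two_blob_grid():
    """Two disjoint PORE blobs of 70 and 30 voxels in a WALL matrix."""
    data = np.full((12, 12, 12), WALL, np.uint8)
    data[1:8, 1:6, 1:3] = PORE  # 7*5*2 = 70 voxels
    data[9:12, 7:12, 10:12] = PORE  # 3*5*2 = 30 voxels
    grid = VoxelGrid(data, 1.0)
    assert (grid.data[1:8, 1:6, 1:3] == PORE).all()
    assert grid.n_pore == 100
    return grid
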