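import numpy as np
import pytest

from gcdmap.io_formats import ImageVolume
from gcdmap.preprocess import VoxelSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(matrix, tr=2.0):
    """VoxelSeries on a trivial line grid, for tests that ignore geometry."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    V = matrix.shape[0]
    voxel_index = np.column_stack([np.arange(V), np.zeros(V, int), np.zeros(V, int)])
    return VoxelSeries(matrix, voxel_index, tr)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def small_volume(rng):
    data = rng.normal(size=(6, 5, 4, 40))
    return ImageVolume(data, np.diag([3.0, 3.0, 3.0, 1.0]), tr_seconds=2.0)


@pytest.fixture
def small_mask():
    mask = np.zeros((6, 5, 4))
    mask[1:5, 1:4, 1:3] = 1.0
    return ImageVolume(mask, np.diag([3.0, 3.0, 3.0, 1.0]))


def simulate_var1(companion, T, seed, burn=100, noise_sd=1.0):
    """Reference VAR(1) sampler used as an independent oracle in tests."""
    rng = np.random.default_rng(seed)
    V = companion.shape[0]
    x = np.zeros(V)
    out = np.empty((T + burn, V))
    for t in range(T + burn):
        x = companion @ x + rng.normal(0, noise_sd, size=V)
        out[t] = x
    return out[burn:].T  # V x T


@pytest.fixture
def var1_sampler():
    return simulate_var1
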