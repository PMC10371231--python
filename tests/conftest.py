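import numpy as np
import pytest

from glymphflow.grids import ImageGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return ImageGrid((8, 8, 8), 0.3)


def gaussian_blob(dims, center, width=3.0, amplitude=30.0):
    """Analytic Gaussian profile on a voxel grid (index coordinates)."""
    x = np.stack(
        np.meshgrid(*[np.arange(float(d)) for d in dims], indexing="ij"), axis=-1
    )
    r2 = np.sum((x - np.asarray(center, float)) ** 2, axis=-1)
    return amplitude * np.exp(-0.5 * r2 / width**2)


@pytest.fixture
def translated_gaussian_pair():
    """Two 32^3 Gaussians (width 3 voxels) displaced 4 voxels along x, floored."""
    dims = (32, 32, 32)
    rho0 = gaussian_blob(dims, (13.5, 15.5, 15.5)) + 1e-3
    rho1 = gaussian_blob(dims, (17.5, 15.5, 15.5)) + 1e-3
    return rho0, rho1, 4.0
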