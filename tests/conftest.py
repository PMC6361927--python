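import numpy as np
import pytest
from scipy import ndimage

from vimloc.synthetic_anatomy import PhantomSpec, generate_subject
from vimloc.volume_io import ROIMask, VoxelGrid


@pytest.fixture(scope="session")
def default_subject():
    """One default-spec phantom subject shared across test modules."""
    return generate_subject(PhantomSpec(), seed=7)


@pytest.fixture
def unit_grid():
    """Small isotropic 0.4 mm grid, mirror-symmetric about x = 0."""
    return VoxelGrid((24, 24, 24), (0.4, 0.4, 0.4), (-4.6, -4.6, -4.6))


def random_blob_mask(grid: VoxelGrid, seed: int, threshold: float = 1.0) -> ROIMask:
    """A random connected-ish blob: thresholded smoothed Gaussian noise.

    Retries with lower thresholds until the mask is nonempty and non-flat
    in x and y (so the eight-way subdivision is defined).
    """
    rng = np.random.default_rng(seed)
    noise = ndimage.gaussian_filter(rng.normal(size=grid.shape), sigma=2.0)
    for thr in (threshold, 0.5, 0.2, 0.0):
        data = noise > thr * noise.std()
        if data.sum() >= 8:
            idx = np.argwhere(data)
            span = idx.max(axis=0) - idx.min(axis=0)
            if span[0] > 0 and span[1] > 0:
                return ROIMask(grid, data)
    raise AssertionError("could not build a usable random mask")
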