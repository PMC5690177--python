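import dataclasses

import numpy as np
import pytest

from brainplan.core import BinaryMask, ImageGeometry
from brainplan.phantom import PhantomSpec, generate_phantom
from brainplan.segmentation import segment_all


def dice_masks(a: BinaryMask, b: BinaryMask) -> float:
    av, bv = a.voxels, b.voxels
    return 2.0 * np.logical_and(av, bv).sum() / (av.sum() + bv.sum())


@pytest.fixture(scope="session")
def default_phantom():
    """One clean 1 mm phantom with ground truth, shared across tests."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_segmentation(default_phantom):
    ct, _ = default_phantom
    return segment_all(ct)


@pytest.fixture(scope="session")
def coarse_phantom():
    """A 2 mm phantom for I/O and matching tests where resolution is moot."""
    spec = PhantomSpec(grid_shape=(80, 98, 86), spacing_mm=(2.0, 2.0, 2.0))
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_coarse_phantom():
    """Integer-HU phantom: DICOM int16 round-trips must be exact."""
    spec = PhantomSpec(grid_shape=(80, 98, 86), spacing_mm=(2.0, 2.0, 2.0),
                       noise_hu_sigma=0.0)
    return generate_phantom(spec)


def make_mask(grid: np.ndarray, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return BinaryMask(grid, ImageGeometry(spacing_mm=spacing, origin_mm=origin))


def random_blob_mask(rng: np.random.Generator, shape=(14, 14, 14),
                     spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    """Small random connected-ish blob for oracle comparisons."""
    from scipy import ndimage

    grid = np.zeros(shape, dtype=bool)
    n_seeds = rng.integers(1, 4)
    for _ in range(n_seeds):
        c = rng.integers(3, np.array(shape) - 3)
        r = rng.integers(2, 5)
        idx = np.indices(shape)
        d2 = sum((idx[a] - c[a]) ** 2 for a in range(3))
        grid |= d2 <= r**2
    grid = ndimage.binary_dilation(grid, iterations=int(rng.integers(0, 2)))
    return make_mask(grid, spacing=spacing)
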