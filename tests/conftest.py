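from __future__ import annotations

import numpy as np
import pytest

from segnoninfer import BinaryMask3D

SPACINGS = [(1.0, 1.0, 1.0), (3.0, 0.45, 0.45), (2.0, 1.5, 1.0)]


def random_mask(rng: np.random.Generator, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0),
                p: float = 0.3, blobby: bool = True) -> BinaryMask3D:
    """Random mask; with blobby=True a thresholded smoothed field (connected-ish)."""
    if blobby:
        from scipy.ndimage import gaussian_filter

        field = gaussian_filter(rng.standard_normal(shape), sigma=1.0)
        thresh = np.quantile(field, 1.0 - p)
        vox = field > thresh
    else:
        vox = rng.random(shape) < p
    return BinaryMask3D(vox, spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cube_pair():
    """4x4x4 cube and the same cube shifted 2 voxels along axis 0 (8^3 grid)."""
    a = np.zeros((8, 8, 8), dtype=bool)
    a[1:5, 2:6, 2:6] = True
    b = np.zeros((8, 8, 8), dtype=bool)
    b[3:7, 2:6, 2:6] = True
    return BinaryMask3D(a, (1.0, 1.0, 1.0)), BinaryMask3D(b, (1.0, 1.0, 1.0))


@pytest.fixture
def empty_mask():
    return BinaryMask3D(np.zeros((6, 6, 6), dtype=bool), (1.0, 1.0, 1.0))
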