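import numpy as np
import pytest

from che_radiomics.imaging_io import ImageVolume, ROIMask, ROIVoxels, apply_mask
from che_radiomics.synthetic_data import CohortConfig, ellipsoid_mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    data = rng.normal(500, 100, size=(12, 12, 12))
    return ImageVolume(data=data, spacing=(1.0, 1.0, 1.0), subject_id="s0000")


@pytest.fixture
def small_mask():
    return ROIMask(name="right-Lc1", data=ellipsoid_mask((12, 12, 12)))


@pytest.fixture
def small_roi(small_volume, small_mask) -> ROIVoxels:
    return apply_mask(small_volume, small_mask)


def roi_from_values(values_3d, mask=None) -> ROIVoxels:
    """Build an ROIVoxels directly from a dense grid (full mask by default)."""
    grid = np.asarray(values_3d, dtype=float)
    m = np.ones(grid.shape, dtype=bool) if mask is None else np.asarray(mask) > 0
    return ROIVoxels(values=grid[m], grid=grid.copy(), mask=m,
                     bounding_box=tuple(slice(0, s) for s in grid.shape))


@pytest.fixture
def tiny_cohort_config():
    return CohortConfig(
        n_che=6, n_nche=6, roi_names=("right-Lc1", "left-Lc1"),
        effect_rois=("right-Lc1",), roi_shape=(10, 10, 10),
        intensity_shift=80.0, variance_ratio=2.0, smoothness_ratio=1.6,
        seed=7)
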