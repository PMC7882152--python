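"""NIfTI volume/mask I/O and ROI extraction.

Volumes and masks must arrive on a common voxel grid (registration and
atlas reslicing are upstream of this package).  ROI extraction is masked
*selection*: background voxels are excluded from all downstream statistics,
never treated as zero intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

#: Minimum in-mask voxel count for texture statistics to be meaningful.
MIN_ROI_VOXELS = 27


class AlignmentError(ValueError):
    """Mask and volume do not share a voxel grid."""


class ValidationError(ValueError):
    """Input violates a structural invariant (non-finite, empty, too small)."""


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing (mm) and subject identity."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(f"volume '{self.subject_id}' contains non-finite voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"voxel spacing must be positive, got {self.spacing}")


@dataclass
class ROIMask:
    """A named binary mask on the same grid as its volume."""

    name: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0.5
        n = int(self.data.sum())
        if n == 0:
            raise ValidationError(f"mask '{self.name}' is empty")
        if n < MIN_ROI_VOXELS:
            raise ValidationError(
                f"mask '{self.name}' has {n} voxels; minimum for texture "
                f"statistics is {MIN_ROI_VOXELS}"
            )


@dataclass
class ROIVoxels:
    """Intensities of one ROI plus the cropped grid that preserves 3D adjacency.

    ``grid`` holds the intensities inside the tight bounding box of the mask;
    ``mask`` flags which of those voxels belong to the ROI.  Out-of-mask
    voxels carry no intensity information for any downstream statistic.
    """

    values: np.ndarray
    grid: np.ndarray
    mask: np.ndarray
    bounding_box: tuple[slice, slice, slice]


def read_volume(path: str | Path, subject_id: str | None = None) -> ImageVolume:
    """Read a NIfTI-1 volume; spacing is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
    try:
        return ImageVolume(data=data, spacing=spacing, subject_id=sid)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_mask(path: str | Path, name: str | None = None) -> ROIMask:
    """Read a NIfTI-1 mask; any voxel value > 0.5 is treated as in-mask."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if name is None:
        # convention: <subject>_<roiname>.nii[.gz]
        stem = Path(path).name.split(".")[0]
        name = stem.split("_", 1)[1] if "_" in stem else stem
    try:
        return ROIMask(name=name, data=data)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_volume(path: str | Path, data: np.ndarray,
                 spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a 3D array as NIfTI-1 with the given isotropic-capable spacing."""
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def apply_mask(volume: ImageVolume, mask: ROIMask) -> ROIVoxels:
    """Extract ROI voxels from a volume by masked selection.

    Returns the in-mask intensities together with the cropped grid (tight
    bounding box) so texture matrices can use 3D lattice adjacency.
    """
    if volume.data.shape != mask.data.shape:
        raise AlignmentError(
            f"volume '{volume.subject_id}' shape {volume.data.shape} does not "
            f"match mask '{mask.name}' shape {mask.data.shape}"
        )
    m = mask.data
    if not m.any():
        raise ValidationError(f"mask '{mask.name}' has empty intersection")
    idx = np.nonzero(m)
    bbox = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    return ROIVoxels(
        values=volume.data[m],
        grid=volume.data[bbox].copy(),
        mask=m[bbox].copy(),
        bounding_box=bbox,
    )
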