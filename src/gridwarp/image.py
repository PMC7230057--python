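"""3D scalar image volumes in a world (mm) coordinate frame.

The package works in an axis-aligned right-handed world frame whose origin
sits at the phantom isocenter.  A voxel (i, j, k) is centered at
``origin + (i, j, k) * spacing``.  All point arithmetic is done in mm;
voxel indices appear only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["ImageVolume", "load_nifti", "save_nifti"]


@dataclass
class ImageVolume:
    """A 3D scalar array plus the metadata placing it in the world frame.

    Parameters
    ----------
    intensities:
        3D float array, indexed (i, j, k).
    voxel_spacing:
        Voxel size in mm along each axis; strictly positive.
    origin:
        World coordinate (mm) of the center of voxel (0, 0, 0).
    modality_tag:
        ``"reference"`` for the geometric ground-truth (CT-like) volume,
        ``"observed"`` for a distorted (MR-like) acquisition.
    """

    intensities: np.ndarray
    voxel_spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    modality_tag: str = "observed"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.modality_tag not in ("reference", "observed"):
            raise ValueError("modality_tag must be 'reference' or 'observed'")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of fractional voxel indices, shape (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return np.asarray(self.origin) + idx * np.asarray(self.voxel_spacing)

    def voxel_indices(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points (mm), shape (n, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return (pts - np.asarray(self.origin)) / np.asarray(self.voxel_spacing)

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of the voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.voxel_spacing[a]
            for a in range(3)
        )

    def sample(self, points: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Interpolate intensities at world points (mm)."""
        idx = self.voxel_indices(points)
        return ndimage.map_coordinates(
            self.intensities, idx.T, order=order, mode="constant", cval=cval
        )

    def copy_with(self, intensities: np.ndarray, **kwargs) -> "ImageVolume":
        return replace(self, intensities=intensities, **kwargs)

    @property
    def center(self) -> np.ndarray:
        """World coordinate of the geometric center of the field of view."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.voxel_spacing
        )


def save_nifti(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume to NIfTI; spacing/origin go into the affine."""
    affine = np.diag(list(volume.voxel_spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.intensities.astype(np.float32), affine)
    img.header["descrip"] = volume.modality_tag.encode()[:79]
    nib.save(img, str(path))


def load_nifti(path: str | Path, modality_tag: str | None = None) -> ImageVolume:
    """Read a NIfTI volume written by :func:`save_nifti` (axis-aligned affine)."""
    img = nib.load(str(path))
    affine = img.affine
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3])), atol=1e-6):
        raise ValueError("only axis-aligned volumes are supported")
    spacing = tuple(np.diag(affine[:3, :3]))
    if modality_tag is None:
        descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
        modality_tag = descrip if descrip in ("reference", "observed") else "observed"
    return ImageVolume(
        intensities=np.asarray(img.dataobj, dtype=np.float64),
        voxel_spacing=spacing,
        origin=tuple(affine[:3, 3]),
        modality_tag=modality_tag,
    )
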