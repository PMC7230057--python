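"""Cubic B-spline free-form deformation transforms.

A deformation T(x) = x + u(x) is parameterized by 3-vector displacements on
a coarse regular control-point lattice; u(x) is the tensor-product cubic
B-spline interpolation of those coefficients.  At any point only the 4x4x4
surrounding control points contribute.  Outside the lattice support the
displacement is continued by the natural polynomial extension of the
boundary spline pieces, so transformed points far from the phantom remain
finite and smooth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image import ImageVolume

__all__ = ["BSplineTransform", "transform_points", "dense_displacement"]

# Uniform cubic B-spline blending polynomials for local coordinate s in
# [0, 1): weight of control point (i0 - 1 + j) is _BLEND[j](s).  Evaluating
# the same polynomials at s outside [0, 1) (clamped window) realizes the
# natural polynomial extrapolation.
def _blend_weights(s: np.ndarray) -> np.ndarray:
    """The four cubic blending weights, shape s.shape + (4,)."""
    s = np.asarray(s, dtype=np.float64)
    s2, s3 = s * s, s * s * s
    w = np.empty(s.shape + (4,))
    w[..., 0] = (1 - 3 * s + 3 * s2 - s3) / 6.0  # (1-s)^3 / 6
    w[..., 1] = (4 - 6 * s2 + 3 * s3) / 6.0
    w[..., 2] = (1 + 3 * s + 3 * s2 - 3 * s3) / 6.0
    w[..., 3] = s3 / 6.0
    return w


def _blend_weights_deriv(s: np.ndarray) -> np.ndarray:
    """d/ds of the four blending weights (units: per grid cell)."""
    s = np.asarray(s, dtype=np.float64)
    s2 = s * s
    w = np.empty(s.shape + (4,))
    w[..., 0] = (-3 + 6 * s - 3 * s2) / 6.0
    w[..., 1] = (-12 * s + 9 * s2) / 6.0
    w[..., 2] = (3 + 6 * s - 9 * s2) / 6.0
    w[..., 3] = 3 * s2 / 6.0
    return w


@dataclass
class BSplineTransform:
    """Control-point lattice + displacement coefficients (mm).

    ``coefficients`` has shape (3, nx, ny, nz); zero coefficients give the
    identity mapping.  ``grid_spacing`` at the finest registration level is
    the final grid spacing (FGS).
    """

    grid_origin: tuple[float, float, float]
    grid_spacing: tuple[float, float, float]
    coefficients: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.ndim != 4 or self.coefficients.shape[0] != 3:
            raise ValueError("coefficients must have shape (3, nx, ny, nz)")
        if any(n < 4 for n in self.coefficients.shape[1:]):
            raise ValueError("control grid needs at least 4 points per axis")
        self.grid_origin = tuple(float(v) for v in self.grid_origin)
        self.grid_spacing = tuple(float(v) for v in self.grid_spacing)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.coefficients.shape[1:]

    def _windows(self, points: np.ndarray):
        """Per-axis window start indices (n,) and local offsets s (n,)."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        i0s, offs = [], []
        for a in range(3):
            u = (pts[:, a] - self.grid_origin[a]) / self.grid_spacing[a]
            i0 = np.floor(u).astype(np.int64)
            # clamp so the 4-point window stays inside the lattice; the
            # blend polynomials then extrapolate for out-of-support points
            i0 = np.clip(i0, 1, self.grid_shape[a] - 3)
            i0s.append(i0)
            offs.append(u - i0)
        return i0s, offs

    def weights_and_indices(self, points: np.ndarray):
        """Flat lattice indices (n, 64) and tensor weights (n, 64)."""
        i0s, offs = self._windows(points)
        w = [_blend_weights(s) for s in offs]  # each (n, 4)
        weights = (w[0][:, :, None, None] * w[1][:, None, :, None] * w[2][:, None, None, :]).reshape(
            len(offs[0]), 64
        )
        offsets = np.arange(-1, 3)
        nx, ny, nz = self.grid_shape
        ix = i0s[0][:, None] + offsets  # (n, 4)
        iy = i0s[1][:, None] + offsets
        iz = i0s[2][:, None] + offsets
        flat = (
            ix[:, :, None, None] * (ny * nz) + iy[:, None, :, None] * nz + iz[:, None, None, :]
        ).reshape(len(weights), 64)
        return flat, weights

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """u(x) in mm at world points, shape (n, 3)."""
        flat, weights = self.weights_and_indices(points)
        cflat = self.coefficients.reshape(3, -1)
        return np.stack([ (cflat[c][flat] * weights).sum(axis=1) for c in range(3)], axis=1)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts + self.displacement(pts)

    def to_manifest(self) -> dict:
        return {
            "grid_origin_mm": list(self.grid_origin),
            "grid_spacing_mm": list(self.grid_spacing),
            "grid_shape": list(self.grid_shape),
            "coefficients_mm": self.coefficients.tolist(),
            "spline_order": 3,
            "extrapolation": "natural-polynomial",
            "meta": self.meta,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_manifest()))

    @classmethod
    def from_manifest(cls, manifest: dict) -> "BSplineTransform":
        return cls(
            grid_origin=tuple(manifest["grid_origin_mm"]),
            grid_spacing=tuple(manifest["grid_spacing_mm"]),
            coefficients=np.asarray(manifest["coefficients_mm"], dtype=float),
            meta=manifest.get("meta", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "BSplineTransform":
        return cls.from_manifest(json.loads(Path(path).read_text()))

    @classmethod
    def identity(
        cls,
        grid_origin: tuple[float, float, float],
        grid_spacing: tuple[float, float, float],
        grid_shape: tuple[int, int, int],
    ) -> "BSplineTransform":
        return cls(grid_origin, grid_spacing, np.zeros((3, *grid_shape)))


def transform_points(transform: BSplineTransform, points: np.ndarray) -> np.ndarray:
    """Map world points x -> x + u(x) through the deformation."""
    return transform.apply(points)


def dense_displacement(transform: BSplineTransform, grid: ImageVolume) -> np.ndarray:
    """Per-voxel displacement vectors (mm) on a volume's grid.

    Returns an array of shape ``grid.shape + (3,)`` suitable for 3-component
    NIfTI export; evaluated in slabs to bound memory.
    """
    shape = grid.shape
    out = np.empty(shape + (3,), dtype=np.float64)
    jj, kk = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    jk = np.stack([jj.ravel(), kk.ravel()], axis=1)
    for i in range(shape[0]):
        idx = np.column_stack([np.full(len(jk), i), jk])
        pts = grid.world_coordinates(idx)
        out[i] = transform.displacement(pts).reshape(shape[1], shape[2], 3)
    return out
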