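"""Synthetic phantom acquisitions with analytically known distortion.

Real scanner distortions (field inhomogeneity, gradient nonlinearity) are
smooth, small (a few mm at most inside a head-sized volume) and strongest
far from the isocenter.  This module emulates them with smooth analytic
vector fields, voxelizes the grid phantom under two contrasts — a
hyposignal grid in a signal-producing oil background (MR-like "observed")
or a hyperdense grid in a lucent background (CT-like "reference") — and
warps volumes through the field so every landmark has a known true
position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import PhantomGeometry
from .image import ImageVolume

__all__ = [
    "AnalyticDistortion",
    "make_distortion_field",
    "random_smooth_field",
    "voxelize_phantom",
    "warp_volume",
    "true_cp_positions",
    "DistortionTooLargeError",
    "CONTRAST_DEFAULTS",
]

# Only relative contrast matters to the pipeline; these defaults mimic
# paraffin oil vs polylactide on T1-weighted MR and soft-tissue CT.
CONTRAST_DEFAULTS = {
    "observed": (1000.0, 50.0),  # (background, grid)
    "reference": (-100.0, 120.0),
}


class DistortionTooLargeError(RuntimeError):
    """The fixed-point inversion of the warp did not converge."""


@dataclass
class AnalyticDistortion:
    """A smooth ground-truth displacement field d(x), world mm -> mm.

    Two bases are supported:

    ``polynomial``
        ``d_i(x) = c_i + sum_j A_ij x_j + sum_jk Q_ijk x_j x_k`` with
        coefficients ``{"const": (3,), "linear": (3,3), "quadratic": (3,3,3)}``
        (missing keys default to zero).
    ``radial-harmonic``
        ``d(x) = (sum_n c_n r^n) r_hat`` with coefficients mapping integer
        order ``n`` to ``c_n`` (mm^(1-n)); purely radial, mimicking
        gradient-nonlinearity-style growth away from the isocenter.
    """

    basis: str
    coefficients: dict
    domain_radius: float
    meta: dict = field(default_factory=dict)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        if self.basis == "polynomial":
            d = np.zeros_like(pts)
            c = self.coefficients.get("const")
            if c is not None:
                d += np.asarray(c, dtype=float)
            a = self.coefficients.get("linear")
            if a is not None:
                d += pts @ np.asarray(a, dtype=float).T
            q = self.coefficients.get("quadratic")
            if q is not None:
                d += np.einsum("ijk,nj,nk->ni", np.asarray(q, dtype=float), pts, pts)
            return d
        if self.basis == "radial-harmonic":
            r = np.linalg.norm(pts, axis=1)
            mag = np.zeros_like(r)
            for order, coef in self.coefficients.items():
                mag += float(coef) * r ** int(order)
            with np.errstate(invalid="ignore", divide="ignore"):
                rhat = np.where(r[:, None] > 0, pts / np.maximum(r, 1e-300)[:, None], 0.0)
            return mag[:, None] * rhat
        raise ValueError(f"unknown basis {self.basis!r}")

    def max_magnitude(self, n_samples: int = 4096, seed: int = 0) -> float:
        """Max |d| over a dense quasi-random sample of the spherical domain."""
        rng = np.random.default_rng(seed)
        u = rng.normal(size=(n_samples, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = self.domain_radius * rng.random(n_samples) ** (1 / 3)
        pts = u * r[:, None]
        # include the boundary shell where smooth fields usually peak
        pts = np.vstack([pts, u[: n_samples // 4] * self.domain_radius])
        return float(np.linalg.norm(self(pts), axis=1).max())

    def scaled(self, factor: float) -> "AnalyticDistortion":
        """The same field with every coefficient multiplied by ``factor``."""
        if self.basis == "polynomial":
            coeffs = {k: np.asarray(v, dtype=float) * factor for k, v in self.coefficients.items()}
        else:
            coeffs = {k: float(v) * factor for k, v in self.coefficients.items()}
        return AnalyticDistortion(self.basis, coeffs, self.domain_radius, dict(self.meta))

    def to_manifest(self) -> dict:
        coeffs = {
            str(k): (np.asarray(v).tolist() if self.basis == "polynomial" else float(v))
            for k, v in self.coefficients.items()
        }
        return {
            "basis": self.basis,
            "coefficients": coeffs,
            "domain_radius_mm": self.domain_radius,
            "meta": self.meta,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_manifest()))

    @classmethod
    def from_manifest(cls, manifest: dict) -> "AnalyticDistortion":
        basis = manifest["basis"]
        raw = manifest["coefficients"]
        if basis == "polynomial":
            coeffs = {k: np.asarray(v, dtype=float) for k, v in raw.items()}
        else:
            coeffs = {int(k): float(v) for k, v in raw.items()}
        return cls(basis, coeffs, manifest["domain_radius_mm"], manifest.get("meta", {}))


def make_distortion_field(
    basis: str, coefficients: dict, domain_radius: float
) -> AnalyticDistortion:
    """Construct an analytic field and record its max |d| over the domain."""
    for v in coefficients.values():
        if not np.all(np.isfinite(np.asarray(v, dtype=float))):
            raise ValueError("coefficients must be finite")
    d = AnalyticDistortion(basis=basis, coefficients=coefficients, domain_radius=domain_radius)
    d.meta["max_magnitude_mm"] = d.max_magnitude()
    return d


def random_smooth_field(
    seed: int, max_magnitude: float, domain_radius: float
) -> AnalyticDistortion:
    """A random smooth polynomial field scaled to a given peak magnitude.

    Draws random constant, linear and quadratic coefficients, then rescales
    so the densely-sampled max |d| inside ``domain_radius`` equals
    ``max_magnitude`` — the stand-in for one scanner's distortion pattern.
    """
    rng = np.random.default_rng(seed)
    coeffs = {
        "const": rng.normal(0, 1.0, size=3),
        "linear": rng.normal(0, 1.0 / domain_radius, size=(3, 3)),
        "quadratic": rng.normal(0, 1.0 / domain_radius**2, size=(3, 3, 3)),
    }
    raw = AnalyticDistortion("polynomial", coeffs, domain_radius)
    peak = raw.max_magnitude()
    out = raw.scaled(max_magnitude / peak)
    out.meta["max_magnitude_mm"] = out.max_magnitude()
    out.meta["seed"] = int(seed)
    return out


def voxelize_phantom(
    geometry: PhantomGeometry,
    voxel_spacing: tuple[float, float, float] | float,
    contrast: str = "observed",
    intensity_levels: tuple[float, float] | None = None,
    fov_margin: float = 12.0,
) -> ImageVolume:
    """Rasterize the grid phantom onto a voxel grid.

    A voxel takes the grid intensity iff its center lies within
    ``bar_thickness/2`` of some bar axis in the Chebyshev (slab) sense —
    bars have square cross-sections.  The field of view is the grid extent
    padded by ``fov_margin`` per side, filled with the background medium.
    """
    if np.isscalar(voxel_spacing):
        voxel_spacing = (float(voxel_spacing),) * 3
    spacing = tuple(float(s) for s in voxel_spacing)
    if max(spacing) > geometry.bar_thickness:
        raise ValueError(
            f"voxel spacing {spacing} exceeds bar thickness {geometry.bar_thickness} mm; "
            "bars would not be resolvable"
        )
    if intensity_levels is None:
        intensity_levels = CONTRAST_DEFAULTS[contrast]
    background, grid_level = intensity_levels

    half_extent = np.asarray(geometry.grid_extent) / 2.0 + fov_margin
    shape = tuple(int(np.ceil(2 * half_extent[a] / spacing[a])) + 1 for a in range(3))
    # voxel centers sit half a voxel off the lattice planes, so bar surfaces
    # fall between samples: rendered bar volume is unbiased and no voxel
    # center lies exactly on a material boundary
    origin = tuple(-(shape[a] - 1) / 2.0 * spacing[a] + spacing[a] / 2.0 for a in range(3))
    axes_coords = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]

    half_bar = geometry.bar_thickness / 2.0 + 1e-9
    mask = np.zeros(shape, dtype=bool)

    # Mark each bar as an axis-aligned box.  Bars run along `axis` through
    # every transverse lattice position carrying vertices; the along-axis
    # span is that line's vertex range (trimmed grids have shorter bars).
    verts = geometry.vertices
    lat = geometry.lattice_indices
    for axis in range(3):
        others = [a for a in range(3) if a != axis]
        keys = lat[:, others]
        uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
        for line_id in range(len(uniq)):
            sel = inverse == line_id
            line_pts = verts[sel]
            u, v = line_pts[0, others[0]], line_pts[0, others[1]]
            lo, hi = line_pts[:, axis].min(), line_pts[:, axis].max()
            if hi <= lo:  # isolated vertex: still a small cube of material
                lo, hi = lo - half_bar, hi + half_bar
            bounds = [None, None, None]
            bounds[axis] = (lo - 1e-9, hi + 1e-9)
            bounds[others[0]] = (u - half_bar, u + half_bar)
            bounds[others[1]] = (v - half_bar, v + half_bar)
            sl = tuple(
                slice(
                    np.searchsorted(axes_coords[a], bounds[a][0], side="left"),
                    np.searchsorted(axes_coords[a], bounds[a][1], side="right"),
                )
                for a in range(3)
            )
            mask[sl] = True

    intensities = np.full(shape, background, dtype=np.float64)
    intensities[mask] = grid_level
    return ImageVolume(
        intensities=intensities,
        voxel_spacing=spacing,
        origin=origin,
        modality_tag=contrast,
        meta={"grid_voxel_fraction": float(mask.mean())},
    )


def warp_volume(
    volume: ImageVolume,
    distortion: AnalyticDistortion,
    noise_sigma: float = 0.0,
    seed: int = 0,
    order: int = 1,
    tol: float = 0.01,
    max_iter: int = 60,
) -> ImageVolume:
    """Warp a volume through T(x) = x + d(x) and add Gaussian noise.

    The output intensity at world point x is the input sampled at
    ``T^{-1}(x)``, with the inverse computed per voxel by fixed-point
    iteration ``y <- x - d(y)`` to a residual below ``tol`` mm.  The run is
    deterministic for a fixed seed.
    """
    shape = volume.shape
    spacing = np.asarray(volume.voxel_spacing)
    origin = np.asarray(volume.origin)
    out = np.empty(shape, dtype=np.float64)

    j_idx, k_idx = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    jk_world = np.stack(
        [origin[1] + j_idx * spacing[1], origin[2] + k_idx * spacing[2]], axis=-1
    ).reshape(-1, 2)

    chunk = max(1, int(4e6 // max(jk_world.shape[0], 1)))
    for start in range(0, shape[0], chunk):
        stop = min(start + chunk, shape[0])
        n_sl = stop - start
        x = np.empty((n_sl * jk_world.shape[0], 3))
        x0 = origin[0] + np.arange(start, stop) * spacing[0]
        x[:, 0] = np.repeat(x0, jk_world.shape[0])
        x[:, 1:] = np.tile(jk_world, (n_sl, 1))

        y = x - distortion(x)  # first-order guess
        converged = False
        for _ in range(max_iter):
            resid = y + distortion(y) - x
            if np.max(np.abs(resid)) < tol:
                converged = True
                break
            y = y - resid
        if not converged:
            raise DistortionTooLargeError(
                f"warp inversion did not reach {tol} mm residual in {max_iter} iterations"
            )
        idx = (y - origin) / spacing
        vals = ndimage.map_coordinates(
            volume.intensities, idx.T, order=order, mode="nearest"
        )
        out[start:stop] = vals.reshape(n_sl, shape[1], shape[2])

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sigma, size=shape)

    meta = dict(volume.meta)
    meta.update({"warp_seed": int(seed), "noise_sigma": float(noise_sigma)})
    return volume.copy_with(out, meta=meta)


def true_cp_positions(
    geometry: PhantomGeometry,
    distortion: AnalyticDistortion | None,
    midpoints: bool = False,
) -> np.ndarray:
    """Ground-truth warped positions {v + d(v)} of vertices (or midpoints)."""
    pts = geometry.cell_midpoints() if midpoints else geometry.vertices
    if distortion is None:
        return pts.copy()
    return pts + distortion(pts)
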