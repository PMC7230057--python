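"""Intensity-based registration: masked rigid pre-alignment and
multiresolution stochastic B-spline nonrigid registration.

The nonrigid stage optimizes the displacements of a cubic B-spline control
lattice with adaptive stochastic gradient descent: each iteration draws a
fresh batch of random sample points inside a mask around the grid, evaluates
the similarity metric (mean squares for same-contrast pairs, Mattes-style
mutual information for cross-modality pairs) on that batch, and takes a step
with a decaying gain.  Resolution levels halve the control spacing and the
image smoothing toward the finest level.  The recovered transform maps
reference (domain) coordinates to observed (target) coordinates, so it
applies directly to reference control points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .bspline import BSplineTransform, _blend_weights_deriv
from .image import ImageVolume

__all__ = [
    "RigidTransform",
    "RegistrationParams",
    "rigid_register",
    "resample_to_reference",
    "bspline_register",
    "make_grid_mask",
    "InsufficientROIError",
    "RegistrationFailureError",
]

# Paper-style search-space bounds for the four swept parameters; values
# outside them are allowed with a warning.
PARAM_BOUNDS = {"fgs": (5.0, 60.0), "nr": (1, 6), "nss": (1000, 7000), "mni": (100, 1000)}


class InsufficientROIError(ValueError):
    """Spherical ROI contains too few voxels to drive the rigid metric."""


class RegistrationFailureError(RuntimeError):
    """Similarity metric became non-finite during optimization."""


@dataclass
class RigidTransform:
    """6-parameter rigid transform: rotations about world axes + translation.

    ``T(x) = R (x - center) + center + translation`` with
    ``R = Rz(rz) @ Ry(ry) @ Rx(rx)`` (angles in radians).
    """

    rotation: tuple[float, float, float]
    translation: tuple[float, float, float]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return mz @ my @ mx

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        c = np.asarray(self.center)
        return (pts - c) @ self.matrix().T + c + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        r = self.matrix().T  # orthonormal
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        # forward: y = R(x-c)+c+t  =>  x = R^T (y-c-t) + c
        inv = RigidTransform(rotation=(0, 0, 0), translation=(0, 0, 0), center=self.center)
        inv._matrix_override = r  # type: ignore[attr-defined]
        inv._trans_override = -r @ t  # type: ignore[attr-defined]
        return inv

    def __post_init__(self) -> None:
        self._matrix_override = None
        self._trans_override = None

    def _apply_full(self, points: np.ndarray) -> np.ndarray:
        if getattr(self, "_matrix_override", None) is None:
            return self.apply(points)
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        c = np.asarray(self.center)
        return (pts - c) @ self._matrix_override.T + c + self._trans_override

    def to_dict(self) -> dict:
        return {
            "rotation_rad": list(self.rotation),
            "translation_mm": list(self.translation),
            "center_mm": list(self.center),
        }


@dataclass
class RegistrationParams:
    """The four swept nonrigid parameters plus metric, seed and mask.

    Defaults are the optimum found by the sequential sweep: final grid
    spacing (FGS) 30 mm, 3 resolutions (NR), 3000 spatial samples per
    iteration (NSS), 500 iterations per level (MNI).
    """

    fgs: float = 30.0
    nr: int = 3
    nss: int = 3000
    mni: int = 500
    metric: str = "mutual-information"  # or "mean-squares"
    seed: int = 0
    mask: np.ndarray | None = None
    bending_weight: float = 0.0
    n_bins: int = 32

    def __post_init__(self) -> None:
        for name, value in (("fgs", self.fgs), ("nr", self.nr), ("nss", self.nss), ("mni", self.mni)):
            lo, hi = PARAM_BOUNDS[name]
            if not (lo <= value <= hi):
                warnings.warn(f"{name}={value} outside the usual range [{lo}, {hi}]")
        if self.metric not in ("mutual-information", "mean-squares"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def to_dict(self) -> dict:
        return {
            "final_grid_spacing_mm": self.fgs,
            "num_resolutions": self.nr,
            "num_spatial_samples": self.nss,
            "max_iterations": self.mni,
            "metric": self.metric,
            "seed": self.seed,
            "bending_weight": self.bending_weight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegistrationParams":
        return cls(
            fgs=d.get("final_grid_spacing_mm", 30.0),
            nr=d.get("num_resolutions", 3),
            nss=d.get("num_spatial_samples", 3000),
            mni=d.get("max_iterations", 500),
            metric=d.get("metric", "mutual-information"),
            seed=d.get("seed", 0),
            bending_weight=d.get("bending_weight", 0.0),
        )


# ---------------------------------------------------------------------------
# rigid stage
# ---------------------------------------------------------------------------

def _roi_points(fixed: ImageVolume, roi_center: np.ndarray, roi_radius: float, max_points: int):
    """World coordinates + fixed intensities of voxels inside the ROI sphere."""
    axes = fixed.axis_coordinates()
    # bounding box of the sphere in index space
    sl = []
    for a in range(3):
        lo = np.searchsorted(axes[a], roi_center[a] - roi_radius, side="left")
        hi = np.searchsorted(axes[a], roi_center[a] + roi_radius, side="right")
        sl.append((lo, hi))
    ii, jj, kk = np.meshgrid(*[np.arange(lo, hi) for lo, hi in sl], indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    pts = fixed.world_coordinates(idx)
    inside = np.linalg.norm(pts - roi_center, axis=1) <= roi_radius
    idx, pts = idx[inside], pts[inside]
    if len(pts) < 1000:
        raise InsufficientROIError(f"ROI sphere holds only {len(pts)} voxels (< 1000)")
    if len(pts) > max_points:
        stride = int(np.ceil(len(pts) / max_points))
        idx, pts = idx[::stride], pts[::stride]
    vals = fixed.intensities[idx[:, 0], idx[:, 1], idx[:, 2]]
    return pts, vals


def _sample_linear(arr: np.ndarray, volume: ImageVolume, points: np.ndarray) -> np.ndarray:
    idx = volume.voxel_indices(points)
    return ndimage.map_coordinates(arr, idx.T, order=1, mode="nearest")


def _histogram_mi(fvals: np.ndarray, mvals: np.ndarray, bins: int = 32) -> float:
    joint, _, _ = np.histogram2d(fvals, mvals, bins=bins)
    p = joint / joint.sum()
    pf = p.sum(axis=1, keepdims=True)
    pm = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (pf @ pm)[nz])))


def rigid_register(
    moving: ImageVolume,
    fixed: ImageVolume,
    roi_radius: float = 27.0,
    roi_center: np.ndarray | None = None,
    metric: str = "mean-squares",
    max_points: int = 20000,
    smooth_sigmas: tuple[float, ...] = (2.0, 0.0),
) -> RigidTransform:
    """Recover the rigid pose of ``moving`` relative to ``fixed``.

    The metric is evaluated only on voxels whose world coordinates lie
    inside a sphere of ``roi_radius`` (default 27 mm) around the phantom
    center, where distortions are negligible and the pose estimate is not
    biased by them.  Powell search over the 6 parameters, run coarse-to-fine
    over Gaussian smoothing levels.
    """
    if roi_center is None:
        roi_center = fixed.center
    roi_center = np.asarray(roi_center, dtype=float)
    pts, _ = _roi_points(fixed, roi_center, roi_radius, max_points)

    x_opt = np.zeros(6)
    trace = []
    for stage, sigma in enumerate(smooth_sigmas):
        if sigma > 0:
            f_arr = ndimage.gaussian_filter(fixed.intensities, sigma)
            m_arr = ndimage.gaussian_filter(moving.intensities, sigma)
        else:
            f_arr, m_arr = fixed.intensities, moving.intensities
        fvals = _sample_linear(f_arr, fixed, pts)

        def objective(x):
            t = RigidTransform(rotation=tuple(x[:3]), translation=tuple(x[3:]), center=tuple(roi_center))
            mvals = _sample_linear(m_arr, moving, t.apply(pts))
            if metric == "mean-squares":
                return float(np.mean((mvals - fvals) ** 2))
            if metric == "correlation":
                # intensity-polarity-blind: |r| = 1 for any affine relation,
                # including the inverted grid/background contrast of MR vs CT
                r = np.corrcoef(fvals, mvals)[0, 1]
                return 1.0 - abs(float(r))
            return -_histogram_mi(fvals, mvals)

        if stage == 0:
            # translation-only pre-search: the lattice phantom's metric is
            # periodic in translation, so settle the shift before letting
            # rotations move (they couple strongly once off-center)
            res_t = optimize.minimize(
                lambda t3: objective(np.concatenate([x_opt[:3], t3])),
                x_opt[3:],
                method="Powell",
                options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 40},
            )
            x_opt = np.concatenate([x_opt[:3], res_t.x])

        res = optimize.minimize(
            objective,
            x_opt,
            method="Powell",
            options={
                "direc": np.diag([0.02, 0.02, 0.02, 1.0, 1.0, 1.0]),
                "xtol": 1e-6,
                "ftol": 1e-10,
                "maxiter": 60,
            },
        )
        x_opt = res.x
        if sigma == smooth_sigmas[-1]:
            # polish with small search directions for sub-0.1 mm / 0.1 deg
            res = optimize.minimize(
                objective,
                x_opt,
                method="Powell",
                options={
                    "direc": np.diag([0.004, 0.004, 0.004, 0.2, 0.2, 0.2]),
                    "xtol": 1e-7,
                    "ftol": 1e-12,
                    "maxiter": 40,
                },
            )
            x_opt = res.x
        trace.append(float(res.fun))

    out = RigidTransform(
        rotation=tuple(x_opt[:3]), translation=tuple(x_opt[3:]), center=tuple(roi_center)
    )
    out.metric_trace = trace  # type: ignore[attr-defined]
    return out


def resample_to_reference(
    volume: ImageVolume,
    reference: ImageVolume,
    transform: RigidTransform | None = None,
    fill_value: float | None = None,
) -> ImageVolume:
    """Resample ``volume`` onto the reference grid through a rigid transform.

    Output voxel at reference-world point x gets ``volume`` sampled at
    T(x) (linear interpolation); out-of-field voxels get ``fill_value``
    (default: the median intensity of the volume's boundary faces, a robust
    background estimate).
    """
    if fill_value is None:
        faces = np.concatenate(
            [
                volume.intensities[0].ravel(),
                volume.intensities[-1].ravel(),
                volume.intensities[:, 0].ravel(),
                volume.intensities[:, -1].ravel(),
                volume.intensities[:, :, 0].ravel(),
                volume.intensities[:, :, -1].ravel(),
            ]
        )
        fill_value = float(np.median(faces))
    shape = reference.shape
    out = np.empty(shape, dtype=np.float64)
    jj, kk = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    jk = np.stack([jj.ravel(), kk.ravel()], axis=1)
    for i in range(shape[0]):
        idx = np.column_stack([np.full(len(jk), i), jk])
        pts = reference.world_coordinates(idx)
        if transform is not None:
            pts = transform._apply_full(pts)
        vox = volume.voxel_indices(pts)
        vals = ndimage.map_coordinates(
            volume.intensities, vox.T, order=1, mode="constant", cval=fill_value
        )
        out[i] = vals.reshape(shape[1], shape[2])
    return ImageVolume(
        intensities=out,
        voxel_spacing=reference.voxel_spacing,
        origin=reference.origin,
        modality_tag=volume.modality_tag,
        meta=dict(volume.meta),
    )


# ---------------------------------------------------------------------------
# nonrigid stage
# ---------------------------------------------------------------------------

def make_grid_mask(reference: ImageVolume, dilation_mm: float = 3.0) -> np.ndarray:
    """Binary mask enclosing the grid: minority intensity phase, dilated.

    The grid occupies a small volume fraction, so the phase on the minority
    side of the mid-intensity threshold is taken as grid and dilated by
    ``dilation_mm`` (about one bar thickness) to include the bar-background
    interfaces that carry the registration signal.
    """
    arr = reference.intensities
    lo, hi = np.percentile(arr, [1, 99])
    mid = (lo + hi) / 2.0
    above = arr > mid
    grid = above if above.mean() < 0.5 else ~above
    iters = max(1, int(round(dilation_mm / min(reference.voxel_spacing))))
    structure = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_dilation(grid, structure=structure, iterations=iters)


def _beta3_and_deriv(t: np.ndarray):
    """Cubic B-spline kernel and derivative on (-2, 2), zero outside."""
    at = np.abs(t)
    val = np.where(
        at < 1,
        (4 - 6 * at**2 + 3 * at**3) / 6.0,
        np.where(at < 2, (2 - at) ** 3 / 6.0, 0.0),
    )
    dval_abs = np.where(at < 1, (-12 * at + 9 * at**2) / 6.0, np.where(at < 2, -((2 - at) ** 2) / 2.0, 0.0))
    return val, dval_abs * np.sign(t)


class _MeanSquares:
    def __init__(self):
        pass

    def value_and_alpha(self, fvals: np.ndarray, mvals: np.ndarray):
        n = len(fvals)
        diff = mvals - fvals
        return float(np.mean(diff**2)), 2.0 * diff / n


class _MattesMI:
    """Mattes-style mutual information with a cubic Parzen window on the
    moving intensity and hard binning on the fixed intensity."""

    def __init__(self, f_range, m_range, n_bins=32):
        self.n_bins = n_bins
        self.fmin, fmax = f_range
        self.mmin, mmax = m_range
        self.fw = (fmax - self.fmin) / n_bins or 1.0
        self.mw = (mmax - self.mmin) / n_bins or 1.0

    def value_and_alpha(self, fvals: np.ndarray, mvals: np.ndarray):
        n = len(fvals)
        nb = self.n_bins
        fbin = np.clip(((fvals - self.fmin) / self.fw).astype(int), 0, nb - 1)
        # continuous moving-bin coordinate, clipped so the 4-bin Parzen
        # window always fits inside the histogram
        mcont = np.clip((mvals - self.mmin) / self.mw - 0.5, 1.5, nb - 2.5)
        k0 = np.floor(mcont).astype(int)
        kidx = k0[:, None] + np.arange(-1, 3)  # (n, 4)
        t = mcont[:, None] - kidx
        wm, dwm = _beta3_and_deriv(t)

        joint = np.zeros((nb, nb))
        np.add.at(joint, (np.repeat(fbin, 4), kidx.ravel()), wm.ravel())
        joint /= n
        pf = joint.sum(axis=1)
        pm = joint.sum(axis=0)
        nz = joint > 0
        denom = np.outer(pf, pm)
        mi = float(np.sum(joint[nz] * np.log(joint[nz] / denom[nz])))

        # d(-MI)/dm_i = -(1/(n*mw)) sum_k beta3'(mcont - k) * log(p(f_i,k)/pm(k))
        with np.errstate(divide="ignore", invalid="ignore"):
            lt = np.log(joint / pm[None, :])
        lt[~np.isfinite(lt)] = 0.0
        alpha = -(dwm * lt[fbin[:, None], kidx]).sum(axis=1) / (n * self.mw)
        return -mi, alpha


def _level_control_grid(mask_bbox_world, spacing_mm):
    """Control-grid origin/shape covering a world bbox, padded 2 points."""
    lo, hi = mask_bbox_world
    origin, shape = [], []
    for a in range(3):
        n_inner = int(np.ceil((hi[a] - lo[a]) / spacing_mm)) + 1
        n = n_inner + 4  # 2 extra control points per side
        o = lo[a] - 2 * spacing_mm
        origin.append(o)
        shape.append(max(n, 4))
    return tuple(origin), tuple(shape)


def bspline_register(
    domain_volume: ImageVolume,
    target_volume: ImageVolume,
    params: RegistrationParams | None = None,
) -> BSplineTransform:
    """Nonrigid B-spline registration of the reference onto an observed volume.

    Both volumes must live on the same voxel grid (rigidly pre-aligned and
    resampled).  Returns the transform mapping domain (reference) world
    coordinates to target (observed) coordinates, directly applicable to
    reference control points.  Fully deterministic for a fixed seed.
    """
    if params is None:
        params = RegistrationParams()
    if domain_volume.shape != target_volume.shape or not np.allclose(
        domain_volume.voxel_spacing, target_volume.voxel_spacing
    ) or not np.allclose(domain_volume.origin, target_volume.origin):
        raise ValueError("volumes must be pre-aligned on a common grid")

    mask = params.mask if params.mask is not None else make_grid_mask(domain_volume)
    if mask.shape != domain_volume.shape:
        raise ValueError("mask shape must match the volumes")
    mask_idx = np.argwhere(mask)
    if len(mask_idx) == 0:
        raise RegistrationFailureError("empty registration mask")
    mask_pts_lo = domain_volume.world_coordinates(mask_idx.min(axis=0))[0]
    mask_pts_hi = domain_volume.world_coordinates(mask_idx.max(axis=0))[0]
    spacing = np.asarray(domain_volume.voxel_spacing)

    transform: BSplineTransform | None = None
    metric_trace: dict[int, list[float]] = {}

    for level in range(params.nr - 1, -1, -1):
        sigma_vox = 2.0**level / 2.0
        f_arr = ndimage.gaussian_filter(domain_volume.intensities, sigma_vox)
        m_arr = ndimage.gaussian_filter(target_volume.intensities, sigma_vox)
        # moving-image gradient (mm^-1 scale) for the chain rule
        m_grad = np.stack(np.gradient(m_arr, *spacing), axis=0)

        cp_spacing = params.fgs * 2.0**level
        origin, shape = _level_control_grid((mask_pts_lo, mask_pts_hi), cp_spacing)
        new = BSplineTransform.identity(origin, (cp_spacing,) * 3, shape)
        if transform is not None:
            # initialize from the coarser level: interpolate its displacement
            # at the new control points, then recover spline coefficients
            gx = origin[0] + np.arange(shape[0]) * cp_spacing
            gy = origin[1] + np.arange(shape[1]) * cp_spacing
            gz = origin[2] + np.arange(shape[2]) * cp_spacing
            xx, yy, zz = np.meshgrid(gx, gy, gz, indexing="ij")
            cp_pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
            vals = transform.displacement(cp_pts).T.reshape(3, *shape)
            coeffs = np.stack(
                [ndimage.spline_filter(vals[c], order=3, mode="mirror") for c in range(3)]
            )
            new = BSplineTransform(origin, (cp_spacing,) * 3, coeffs)
        transform = new

        if params.metric == "mean-squares":
            metric = _MeanSquares()
        else:
            f_roi = f_arr[mask]
            metric = _MattesMI(
                (float(f_roi.min()), float(f_roi.max())),
                (float(m_arr.min()), float(m_arr.max())),
                n_bins=params.n_bins,
            )

        rng = np.random.default_rng([params.seed, level])
        cflat = transform.coefficients.reshape(3, -1)
        trace = []
        asgd_A, asgd_alpha = 20.0, 0.602
        delta0 = float(spacing.max())  # coefficient step scale: one voxel

        def batch_gradient(coeffs_flat: np.ndarray, it_label: int):
            """Metric value + gradient w.r.t. coefficients on a fresh batch."""
            sel = rng.integers(0, len(mask_idx), size=params.nss)
            jitter = rng.uniform(-0.5, 0.5, size=(params.nss, 3))
            pts = domain_volume.world_coordinates(mask_idx[sel] + jitter)
            fvals = _sample_linear(f_arr, domain_volume, pts)

            flat, weights = transform.weights_and_indices(pts)
            disp = np.stack(
                [(coeffs_flat[c][flat] * weights).sum(axis=1) for c in range(3)], axis=1
            )
            vox = target_volume.voxel_indices(pts + disp)
            mvals = ndimage.map_coordinates(m_arr, vox.T, order=1, mode="nearest")
            grads = np.stack(
                [
                    ndimage.map_coordinates(m_grad[c], vox.T, order=1, mode="nearest")
                    for c in range(3)
                ],
                axis=1,
            )
            value, alpha = metric.value_and_alpha(fvals, mvals)
            if not np.isfinite(value):
                raise RegistrationFailureError(
                    f"non-finite metric at level {level}, iteration {it_label}"
                )
            g = np.zeros_like(coeffs_flat)
            contrib = weights * alpha[:, None]
            for c in range(3):
                np.add.at(g[c], flat.ravel(), (contrib * grads[:, c : c + 1]).ravel())
            return value, g

        # gain estimation by probing the gradient response to delta0-scale
        # random perturbations — robust when the level already starts near
        # its optimum (where the actual gradient is almost zero)
        probe_gmax = []
        for _ in range(2):
            pert = rng.uniform(-delta0, delta0, size=cflat.shape)
            _, gp = batch_gradient(cflat + pert, -1)
            probe_gmax.append(np.abs(gp).max())
        gain_a = delta0 * (asgd_A + 1) ** asgd_alpha / (np.median(probe_gmax) + 1e-30)

        for it in range(params.mni):
            value, g = batch_gradient(cflat, it)
            trace.append(value)
            gamma = gain_a / (asgd_A + it + 1) ** asgd_alpha
            gmax = np.abs(g).max()
            if gamma * gmax > delta0:  # trust region: at most one voxel per step
                gamma = delta0 / gmax
            cflat -= gamma * g
        metric_trace[level] = trace

    transform.meta.update(
        {
            "params": params.to_dict(),
            "metric_trace": {str(k): v for k, v in metric_trace.items()},
            "final_metric": metric_trace[0][-1] if metric_trace.get(0) else None,
        }
    )
    return transform
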