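"""Control-point localization by binary-template normalized cross-correlation.

A grid vertex looks like three orthogonal square-cross-section bars crossing
at a point.  A small binary template of that junction is slid over the
volume with zero-normalized cross-correlation; suprathreshold blobs of the
correlation map are reduced to their correlation-weighted centers of mass,
yielding sub-voxel landmark positions.  Detected points are paired to
reference points by mutual nearest neighbors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import match_template

from .image import ImageVolume

__all__ = [
    "ControlPointSet",
    "CPPairs",
    "build_vertex_template",
    "ncc_match",
    "extract_cp_candidates",
    "pair_control_points",
    "DegenerateTemplateError",
]


class DegenerateTemplateError(ValueError):
    """Template with zero intensity variance cannot be correlated."""


@dataclass
class ControlPointSet:
    """Landmark positions (mm) with per-point low-confidence review flags."""

    points: np.ndarray  # (n, 3) world mm
    ids: np.ndarray  # (n,) ints, unique
    source_tag: str = "detected"  # reference | detected | transformed
    review_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.ids = np.asarray(self.ids, dtype=int)
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("control point ids must be unique")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("control point coordinates must be finite")
        if self.review_flags is None:
            self.review_flags = np.zeros(len(self.ids), dtype=bool)
        else:
            self.review_flags = np.asarray(self.review_flags, dtype=bool)

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_points(cls, points: np.ndarray, source_tag: str = "reference") -> "ControlPointSet":
        points = np.atleast_2d(points)
        return cls(points=points, ids=np.arange(len(points)), source_tag=source_tag)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "z_mm": self.points[:, 2],
                "flag": self.review_flags.astype(int),
            }
        )

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def load_tsv(cls, path: str | Path, source_tag: str = "detected") -> "ControlPointSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            points=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
            ids=df["id"].to_numpy(),
            source_tag=source_tag,
            review_flags=df["flag"].to_numpy().astype(bool),
        )


@dataclass
class CPPairs:
    """Injective matching of detected to reference control points."""

    reference_ids: np.ndarray
    detected_ids: np.ndarray
    displacements: np.ndarray  # (n, 3) mm, detected - reference
    reference_points: np.ndarray  # (n, 3) mm
    unmatched_reference_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    unmatched_detected_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __len__(self) -> int:
        return len(self.reference_ids)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.displacements, axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reference_id": self.reference_ids,
                "detected_id": self.detected_ids,
                "x_mm": self.reference_points[:, 0],
                "y_mm": self.reference_points[:, 1],
                "z_mm": self.reference_points[:, 2],
                "dx_mm": self.displacements[:, 0],
                "dy_mm": self.displacements[:, 1],
                "dz_mm": self.displacements[:, 2],
                "magnitude_mm": self.magnitudes,
            }
        )

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "CPPairs":
        df = pd.read_csv(path, sep="\t")
        return cls(
            reference_ids=df["reference_id"].to_numpy(),
            detected_ids=df["detected_id"].to_numpy(),
            displacements=df[["dx_mm", "dy_mm", "dz_mm"]].to_numpy(),
            reference_points=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        )


def build_vertex_template(
    bar_thickness: float,
    template_size: float,
    voxel_spacing: tuple[float, float, float] | float,
    polarity: str = "grid-dark",
) -> np.ndarray:
    """Binary template of a bar junction: three orthogonal square bars.

    Foreground (1) marks the phase the correlation should peak on:
    ``grid-dark`` puts foreground on the background phase (MR contrast,
    hyposignal grid), ``grid-bright`` on the bars (CT contrast).  Voxel
    counts are forced odd per axis so the center is unambiguous.
    """
    if template_size < bar_thickness:
        raise ValueError("template must be at least one bar thickness wide")
    if np.isscalar(voxel_spacing):
        voxel_spacing = (float(voxel_spacing),) * 3
    shape = []
    for s in voxel_spacing:
        n = int(round(template_size / s))
        if n % 2 == 0:
            n += 1  # adjusted up: odd count keeps the junction centered
        shape.append(max(n, 3))
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, voxel_spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    half = bar_thickness / 2.0 + 1e-9
    in_bar = (
        ((np.abs(yy) <= half) & (np.abs(zz) <= half))
        | ((np.abs(xx) <= half) & (np.abs(zz) <= half))
        | ((np.abs(xx) <= half) & (np.abs(yy) <= half))
    )
    if polarity == "grid-bright":
        return in_bar.astype(np.float64)
    if polarity == "grid-dark":
        return (~in_bar).astype(np.float64)
    raise ValueError(f"unknown polarity {polarity!r}")


def ncc_match(volume: ImageVolume, template: np.ndarray) -> ImageVolume:
    """Zero-normalized cross-correlation of a template over a volume.

    Returns a correlation volume on the input grid.  The coefficient is
    computed only where the template fully fits; the outer margin where it
    does not is assigned -1 (never a peak).
    """
    template = np.asarray(template, dtype=np.float64)
    if template.std() == 0:
        raise DegenerateTemplateError("template has zero variance")
    if any(t > v for t, v in zip(template.shape, volume.shape)):
        raise ValueError("template does not fit within the volume")
    valid = match_template(volume.intensities, template, pad_input=False)
    corr = np.full(volume.shape, -1.0)
    starts = [t // 2 for t in template.shape]
    corr[
        starts[0] : starts[0] + valid.shape[0],
        starts[1] : starts[1] + valid.shape[1],
        starts[2] : starts[2] + valid.shape[2],
    ] = valid
    return volume.copy_with(np.clip(corr, -1.0, 1.0), modality_tag=volume.modality_tag)


def extract_cp_candidates(
    correlation: ImageVolume,
    threshold: float = 0.5,
    min_voxels: int = 3,
    weighted: bool = True,
    low_confidence: float | None = None,
    min_separation: float | None = None,
) -> ControlPointSet:
    """Reduce suprathreshold correlation blobs to sub-voxel landmarks.

    Connected components (26-connectivity) of ``correlation > threshold``
    become one candidate each, located at the correlation-weighted center
    of mass (binary center of mass with ``weighted=False``).  Components
    smaller than ``min_voxels`` are dropped; components whose peak
    correlation is below ``low_confidence`` (default: threshold + 0.1, just
    under the response of a boundary junction) are flagged for review
    rather than dropped.

    With ``min_separation`` (mm) set, candidates are additionally pruned by
    non-maximum suppression: among candidates closer than the separation,
    only the one with the highest peak correlation survives.  On a lattice
    phantom this rejects the weaker responses halfway along the bars while
    keeping every junction (set it between half and one vertex spacing).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    corr = correlation.intensities
    mask = corr > threshold
    if not mask.any():
        import warnings

        warnings.warn("no suprathreshold correlation voxels; returning empty set")
        return ControlPointSet(points=np.empty((0, 3)), ids=np.empty(0, dtype=int))

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n_comp = ndimage.label(mask, structure=structure)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
    keep = np.flatnonzero(sizes >= min_voxels) + 1
    if len(keep) == 0:
        import warnings

        warnings.warn("all correlation components below minimum size")
        return ControlPointSet(points=np.empty((0, 3)), ids=np.empty(0, dtype=int))

    weights = np.where(mask, corr, 0.0) if weighted else mask.astype(float)
    coms = ndimage.center_of_mass(weights, labels, index=keep)
    peaks = np.asarray(ndimage.maximum(corr, labels, index=keep))
    points = correlation.world_coordinates(np.asarray(coms))

    if min_separation is not None and len(points) > 1:
        from scipy.spatial import cKDTree

        order = np.argsort(-peaks)
        tree = cKDTree(points)
        suppressed = np.zeros(len(points), dtype=bool)
        for i in order:
            if suppressed[i]:
                continue
            for j in tree.query_ball_point(points[i], min_separation):
                if j != i and peaks[j] <= peaks[i]:
                    suppressed[j] = True
        points, peaks = points[~suppressed], peaks[~suppressed]

    if low_confidence is None:
        low_confidence = threshold + 0.1
    flags = np.asarray(peaks) < low_confidence
    return ControlPointSet(
        points=points,
        ids=np.arange(len(points)),
        source_tag="detected",
        review_flags=flags,
    )


def pair_control_points(
    reference: ControlPointSet,
    detected: ControlPointSet,
    max_distance: float = 7.5,
) -> CPPairs:
    """Greedy mutual-nearest-neighbor pairing in ascending distance order.

    Every detected point is matched to the closest unclaimed reference
    point (and vice versa); candidate pairs farther than ``max_distance``
    mm apart are rejected.  Displacements are detected - reference.
    """
    if len(reference) == 0 or len(detected) == 0:
        raise ValueError("both control point sets must be non-empty")
    from scipy.spatial import cKDTree

    tree = cKDTree(detected.points)
    k = min(len(detected), 8)
    dists, cols = tree.query(reference.points, k=k, distance_upper_bound=max_distance)
    dists = np.atleast_2d(dists.T).T if dists.ndim == 1 else dists
    cols = np.atleast_2d(cols.T).T if cols.ndim == 1 else cols

    candidates = []
    for ri in range(len(reference)):
        for j in range(k):
            if np.isfinite(dists[ri, j]) and cols[ri, j] < len(detected):
                candidates.append((dists[ri, j], ri, cols[ri, j]))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    ref_taken = np.zeros(len(reference), dtype=bool)
    det_taken = np.zeros(len(detected), dtype=bool)
    pairs = []
    for dist, ri, di in candidates:
        if not ref_taken[ri] and not det_taken[di]:
            ref_taken[ri] = det_taken[di] = True
            pairs.append((ri, di))

    if pairs:
        ref_idx = np.array([p[0] for p in pairs])
        det_idx = np.array([p[1] for p in pairs])
        disp = detected.points[det_idx] - reference.points[ref_idx]
        ref_pts = reference.points[ref_idx]
        ref_ids = reference.ids[ref_idx]
        det_ids = detected.ids[det_idx]
    else:
        ref_ids = det_ids = np.empty(0, dtype=int)
        disp = ref_pts = np.empty((0, 3))
    return CPPairs(
        reference_ids=ref_ids,
        detected_ids=det_ids,
        displacements=disp,
        reference_points=ref_pts,
        unmatched_reference_ids=reference.ids[~ref_taken],
        unmatched_detected_ids=detected.ids[~det_taken],
    )
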