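"""Grid-phantom geometry: the vertex lattice, elementary cells and midpoints.

The phantom is a cubic lattice of solid bars inside a cylindrical
container.  Lattice vertices are the QA landmarks ("control points", CPs);
the centers of the elementary cubes between eight neighboring vertices are
the midpoints used as the overfitting diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PhantomGeometry", "build_grid_geometry", "InvalidGeometryError", "EmptyGridError"]


class InvalidGeometryError(ValueError):
    """Geometry parameters that cannot form a valid grid phantom."""


class EmptyGridError(ValueError):
    """Extent too small to hold even a single lattice spacing."""


@dataclass
class PhantomGeometry:
    """The grid lattice in the world frame (mm), centered on the origin.

    ``vertices`` are world coordinates of the lattice nodes;
    ``lattice_indices`` the corresponding integer (i, j, k) lattice labels;
    ``cells`` index octets of vertices forming complete elementary cubes.
    """

    vertex_spacing: float
    bar_thickness: float
    grid_extent: tuple[float, float, float]
    container_inner_radius: float | None
    vertices: np.ndarray  # (n, 3) world mm
    lattice_indices: np.ndarray  # (n, 3) ints
    cells: np.ndarray  # (m, 8) vertex indices
    meta: dict = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_midpoints(self) -> np.ndarray:
        """Centers of the elementary cubes (mean of each cell's 8 corners)."""
        if self.n_cells == 0:
            return np.empty((0, 3))
        return self.vertices[self.cells].mean(axis=1)

    @property
    def centroid(self) -> np.ndarray:
        """Grid centroid — the phantom isocenter in this package's convention."""
        return self.vertices.mean(axis=0)

    def bar_axes(self) -> list[tuple[int, np.ndarray]]:
        """Bar segments as (axis, coordinates of the two fixed axes).

        A bar runs parallel to ``axis`` through every lattice line that
        carries at least one vertex; returned as the unique fixed-plane
        coordinate pairs per axis.
        """
        out = []
        for axis in range(3):
            others = [a for a in range(3) if a != axis]
            fixed = np.unique(self.vertices[:, others].round(9), axis=0)
            out.append((axis, fixed))
        return out

    def to_manifest(self) -> dict:
        return {
            "vertex_spacing_mm": self.vertex_spacing,
            "bar_thickness_mm": self.bar_thickness,
            "grid_extent_mm": list(self.grid_extent),
            "container_inner_radius_mm": self.container_inner_radius,
            "n_vertices": self.n_vertices,
            "n_cells": self.n_cells,
            "vertices_mm": self.vertices.tolist(),
            "lattice_indices": self.lattice_indices.tolist(),
            "cells": self.cells.tolist(),
            "meta": self.meta,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_manifest()))

    @classmethod
    def from_manifest(cls, manifest: dict) -> "PhantomGeometry":
        return cls(
            vertex_spacing=manifest["vertex_spacing_mm"],
            bar_thickness=manifest["bar_thickness_mm"],
            grid_extent=tuple(manifest["grid_extent_mm"]),
            container_inner_radius=manifest["container_inner_radius_mm"],
            vertices=np.asarray(manifest["vertices_mm"], dtype=float),
            lattice_indices=np.asarray(manifest["lattice_indices"], dtype=int),
            cells=np.asarray(manifest["cells"], dtype=int).reshape(-1, 8),
            meta=manifest.get("meta", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PhantomGeometry":
        return cls.from_manifest(json.loads(Path(path).read_text()))


def build_grid_geometry(
    vertex_spacing: float,
    bar_thickness: float,
    grid_extent: tuple[float, float, float],
    container_inner_radius: float | None = None,
) -> PhantomGeometry:
    """Build the maximal vertex lattice fitting inside ``grid_extent``.

    The lattice is centered on the extent box (whose center is the world
    origin).  The first extent axis is the phantom height (the cylinder
    axis of the container); with ``container_inner_radius`` given, vertices
    whose radial distance from that axis exceeds
    ``container_inner_radius - bar_thickness/2`` are trimmed away.  Cells
    enumerate all elementary cubes whose 8 corners all survive.
    """
    if not (vertex_spacing > bar_thickness > 0):
        raise InvalidGeometryError(
            f"need vertex_spacing > bar_thickness > 0, got {vertex_spacing} / {bar_thickness}"
        )
    extent = tuple(float(e) for e in grid_extent)
    if any(e < vertex_spacing for e in extent):
        raise EmptyGridError(f"extent {extent} smaller than one spacing on some axis")

    # n lattice points per axis: the maximal count with (n-1)*spacing <= extent
    counts = [int(np.floor(e / vertex_spacing + 1e-9)) + 1 for e in extent]
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * vertex_spacing for n in counts
    ]
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in counts], indexing="ij")
    lattice = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    verts = np.stack(
        [axes[0][lattice[:, 0]], axes[1][lattice[:, 1]], axes[2][lattice[:, 2]]], axis=1
    )

    if container_inner_radius is not None:
        r_keep = container_inner_radius - bar_thickness / 2.0
        radial = np.hypot(verts[:, 1], verts[:, 2])  # distance from the height axis
        keep = radial <= r_keep + 1e-9
        verts, lattice = verts[keep], lattice[keep]
        if len(verts) == 0:
            raise EmptyGridError("cylindrical trim removed every vertex")

    # index lookup for cell enumeration
    key = {tuple(l): i for i, l in enumerate(map(tuple, lattice))}
    cells = []
    corners = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]]
    )
    for l in lattice:
        octet = []
        for c in corners:
            idx = key.get(tuple(l + c))
            if idx is None:
                break
            octet.append(idx)
        else:
            cells.append(octet)
    cells_arr = np.asarray(cells, dtype=int).reshape(-1, 8)

    return PhantomGeometry(
        vertex_spacing=float(vertex_spacing),
        bar_thickness=float(bar_thickness),
        grid_extent=extent,
        container_inner_radius=container_inner_radius,
        vertices=verts,
        lattice_indices=lattice,
        cells=cells_arr,
        meta={"lattice_counts": counts},
    )
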