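"""Triangulated vessel surfaces.

A :class:`SurfaceMesh` holds vertex coordinates (mm), triangle connectivity,
outward unit vertex normals, and optional named vertex regions (e.g. an
``inlet_band`` used to normalize wall-shear fields).  Vertex area weights —
one third of the area of each incident triangle — turn per-vertex fields
into surface integrals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

__all__ = ["SurfaceMesh", "surface_mean"]


@dataclass
class SurfaceMesh:
    vertices: np.ndarray  # (V, 3) mm
    triangles: np.ndarray  # (F, 3) int
    vertex_normals: np.ndarray  # (V, 3) outward unit vectors
    region_labels: dict[str, np.ndarray] = field(default_factory=dict)  # name -> vertex indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.triangles = np.asarray(self.triangles, int)
        self.vertex_normals = np.asarray(self.vertex_normals, float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must have shape (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must have shape (F, 3)")
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= len(self.vertices):
            raise ValueError("triangles reference vertices out of range")
        if self.vertex_normals.shape != self.vertices.shape:
            raise ValueError("vertex_normals must match vertices in shape")
        norms = np.linalg.norm(self.vertex_normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("vertex normals must be unit length (within 1e-6)")
        self.region_labels = {
            k: np.asarray(v, int) for k, v in self.region_labels.items()
        }

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangle_areas(self) -> np.ndarray:
        """Area of each triangle (mm^2)."""
        p = self.vertices[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Per-vertex area weight: one third of incident triangle areas (mm^2).

        Degenerate (zero-area) triangles are excluded with a warning.
        """
        areas = self.triangle_areas()
        bad = areas <= 0.0
        if np.any(bad):
            warnings.warn(
                f"excluding {int(bad.sum())} degenerate triangle(s) from area weights",
                stacklevel=2,
            )
            areas = np.where(bad, 0.0, areas)
        w = np.zeros(self.n_vertices)
        np.add.at(w, self.triangles.ravel(), np.repeat(areas / 3.0, 3))
        return w

    def region(self, name: str) -> np.ndarray:
        try:
            return self.region_labels[name]
        except KeyError:
            raise KeyError(
                f"mesh has no region {name!r}; known regions: {sorted(self.region_labels)}"
            ) from None


def surface_mean(field: np.ndarray, mesh: SurfaceMesh, vertices: np.ndarray | None = None) -> float:
    """Vertex-area-weighted mean of a per-vertex scalar field.

    ``vertices`` restricts the average to a subset (e.g. a region); NaN
    entries are excluded from the average.
    """
    field = np.asarray(field, float)
    w = mesh.vertex_areas()
    if vertices is not None:
        idx = np.asarray(vertices, int)
        field = field[idx]
        w = w[idx]
    ok = np.isfinite(field)
    total = w[ok].sum()
    if total <= 0:
        raise ValueError("surface mean undefined: no finite values with positive area")
    return float(np.sum(w[ok] * field[ok]) / total)
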