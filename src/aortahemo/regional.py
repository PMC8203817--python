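"""Regional cross-sectional analysis along a vessel centerline.

Seven analysis planes (labelled ``alpha`` .. ``eta``) are placed at
arc-length offsets, in multiples of the inlet diameter D, from named
centerline landmarks (inlet and the origins of the brachiocephalic, left
common carotid and left subclavian arteries).  Each plane is intersected
with the vessel surface to give a closed ring; per-vertex fields are
interpolated along the ring, sampled at eight circumferential points at 45
degree spacing starting from an anterior reference direction, and averaged
over the plane with perimeter-length weighting.  Group statistics (sample
mean and n-1 standard deviation) compare subject cohorts.

Centerlines and landmark positions are inputs; computing them from imaging
is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mesh import SurfaceMesh

__all__ = [
    "CenterlineTrack",
    "CrossSectionSpec",
    "Ring",
    "RingProfile",
    "SECTION_LABELS",
    "place_sections",
    "slice_ring",
    "ring_profile",
    "group_stats",
]

SECTION_LABELS = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta")


@dataclass
class CenterlineTrack:
    """Polyline centerline (mm) with named landmarks at arc-length positions."""

    points: np.ndarray  # (N, 3) mm
    landmarks: dict[str, float]  # label -> arc length (mm)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("centerline needs at least two 3-D points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline points must be distinct (strictly increasing arc length)")
        self._s = np.concatenate([[0.0], np.cumsum(seg)])
        for name, s in self.landmarks.items():
            if not 0.0 <= s <= self.length:
                raise ValueError(f"landmark {name!r} at s={s} outside [0, {self.length:.3g}]")

    @property
    def length(self) -> float:
        return float(self._s[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Interpolated centerline point at arc length s."""
        self._check(s)
        return np.array([np.interp(s, self._s, self.points[:, k]) for k in range(3)])

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit downstream tangent at arc length s (segment direction)."""
        self._check(s)
        i = min(np.searchsorted(self._s, s, side="right"), len(self._s) - 1)
        d = self.points[i] - self.points[i - 1]
        return d / np.linalg.norm(d)

    def _check(self, s: float) -> None:
        if not 0.0 <= s <= self.length * (1 + 1e-12):
            raise ValueError(
                f"arc length {s:.4g} mm beyond centerline extent [0, {self.length:.4g}]"
            )


@dataclass(frozen=True)
class CrossSectionSpec:
    """One analysis plane: origin, downstream normal, and the circumferential zero."""

    label: str
    origin: np.ndarray
    normal: np.ndarray
    anterior_ref: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        n = np.asarray(self.normal, float)
        a = np.asarray(self.anterior_ref, float)
        if not math.isclose(np.linalg.norm(n), 1.0, rel_tol=1e-6):
            raise ValueError("normal must be a unit vector")
        if not math.isclose(np.linalg.norm(a), 1.0, rel_tol=1e-6):
            raise ValueError("anterior_ref must be a unit vector")
        if abs(float(n @ a)) > 1e-6:
            raise ValueError("anterior_ref must be perpendicular to the normal")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "anterior_ref", a)


def place_sections(
    c: CenterlineTrack,
    D_mm: float,
    aberrant_rsa: bool = False,
    anterior_hint: np.ndarray = (0.0, 1.0, 0.0),
    alpha_sign: float = 1.0,
) -> list[CrossSectionSpec]:
    """Place the seven analysis planes from centerline landmarks.

    Landmarks required: ``inlet``, ``BCA``, ``LCCA``, ``LSA`` (arc lengths of
    the inlet and the three supra-aortic branch origins).  Offsets, in units
    of the inlet diameter D:

    - alpha:   inlet + alpha_sign * 1 D (ascending aorta)
    - beta:    midway between the LCCA and LSA origins (transverse arch)
    - gamma:   1 D past the LSA origin (descending aorta)
    - delta:   2 D past the LSA origin
    - epsilon: 0.5 D before the BCA origin
    - zeta:    0.5 D before the LCCA origin
    - eta:     0.5 D before the LSA origin

    With ``aberrant_rsa`` (a right subclavian arising distally, so the LSA is
    not the last pre-descending branch) gamma and delta are referenced to the
    LCCA origin instead.  ``anterior_hint`` fixes the circumferential zero:
    its projection onto each plane becomes the anterior reference direction.
    """
    if D_mm <= 0:
        raise ValueError("diameter must be positive")
    need = {"inlet", "BCA", "LCCA", "LSA"}
    missing = need - set(c.landmarks)
    if missing:
        raise ValueError(f"missing centerline landmarks: {sorted(missing)}")
    lm = c.landmarks
    desc_ref = lm["LCCA"] if aberrant_rsa else lm["LSA"]
    positions = {
        "alpha": lm["inlet"] + alpha_sign * D_mm,
        "beta": 0.5 * (lm["LCCA"] + lm["LSA"]),
        "gamma": desc_ref + 1.0 * D_mm,
        "delta": desc_ref + 2.0 * D_mm,
        "epsilon": lm["BCA"] - 0.5 * D_mm,
        "zeta": lm["LCCA"] - 0.5 * D_mm,
        "eta": lm["LSA"] - 0.5 * D_mm,
    }
    hint = np.asarray(anterior_hint, float)
    specs = []
    for label in SECTION_LABELS:
        s = positions[label]
        origin = c.point_at(s)
        normal = c.tangent_at(s)
        a = hint - (hint @ normal) * normal
        if np.linalg.norm(a) < 1e-9:
            raise ValueError(f"anterior hint is parallel to the centerline at section {label}")
        specs.append(CrossSectionSpec(label, origin, normal, a / np.linalg.norm(a)))
    return specs


@dataclass
class Ring:
    """Closed plane/surface intersection polyline with interpolated fields."""

    points: np.ndarray  # (M, 3), ordered, not repeating the first point
    values: dict[str, np.ndarray]  # field name -> (M,)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def slice_ring(
    mesh: SurfaceMesh,
    spec: CrossSectionSpec,
    near: np.ndarray,
    fields: dict[str, np.ndarray] | None = None,
) -> Ring:
    """Intersect the surface with a plane and return the ring nearest ``near``.

    Field values are linearly interpolated along the cut edges.  Raises if
    the plane misses the surface or the cut is not a closed loop.
    """
    fields = fields or {}
    near = np.asarray(near, float)
    d = (mesh.vertices - spec.origin) @ spec.normal
    d = np.where(np.abs(d) < 1e-12, 1e-12, d)  # nudge on-plane vertices

    edge_point: dict[tuple[int, int], np.ndarray] = {}
    edge_vals: dict[tuple[int, int], dict[str, float]] = {}
    links: dict[tuple[int, int], set[tuple[int, int]]] = {}

    def edge_key(a: int, b: int) -> tuple[int, int]:
        key = (a, b) if a < b else (b, a)
        if key not in edge_point:
            t = d[key[0]] / (d[key[0]] - d[key[1]])
            edge_point[key] = mesh.vertices[key[0]] + t * (mesh.vertices[key[1]] - mesh.vertices[key[0]])
            edge_vals[key] = {
                name: float(f[key[0]] + t * (f[key[1]] - f[key[0]])) for name, f in fields.items()
            }
        return key

    for tri in mesh.triangles:
        crossed = [
            (a, b)
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0]))
            if d[a] * d[b] < 0
        ]
        if len(crossed) == 2:
            k0, k1 = edge_key(*crossed[0]), edge_key(*crossed[1])
            links.setdefault(k0, set()).add(k1)
            links.setdefault(k1, set()).add(k0)

    if not links:
        raise ValueError(f"plane {spec.label!r} does not intersect the surface")
    bad = [k for k, nbrs in links.items() if len(nbrs) != 2]
    if bad:
        raise ValueError(
            f"open ring at section {spec.label!r}: {len(bad)} cut edge(s) are not "
            "shared by exactly two triangles (non-manifold or boundary cut)"
        )

    # walk connected loops
    unvisited = set(links)
    loops: list[list[tuple[int, int]]] = []
    while unvisited:
        start = unvisited.pop()
        loop = [start]
        prev, cur = None, start
        while True:
            nxt = [k for k in links[cur] if k != prev]
            if not nxt:
                raise ValueError(
                    f"open ring at section {spec.label!r}: the cut is not a closed loop "
                    f"(dangling at edge {cur})"
                )
            prev, cur = cur, nxt[0]
            if cur == start:
                break
            loop.append(cur)
            unvisited.discard(cur)
        loops.append(loop)

    def loop_dist(loop: list[tuple[int, int]]) -> float:
        pts = np.array([edge_point[k] for k in loop])
        return float(np.min(np.linalg.norm(pts - near, axis=1)))

    best = min(loops, key=loop_dist)
    pts = np.array([edge_point[k] for k in best])
    vals = {name: np.array([edge_vals[k][name] for k in best]) for name in fields}
    return Ring(pts, vals)


@dataclass
class RingProfile:
    """Eight circumferential samples and the plane average of one field."""

    label: str
    angles_deg: np.ndarray
    samples: np.ndarray
    plane_average: float
    perimeter: float


def ring_profile(
    ring: Ring, spec: CrossSectionSpec, field_name: str, n_points: int = 8
) -> RingProfile:
    """Sample a ring field at equally spaced circumferential angles.

    Angles are measured around the ring centroid from the anterior reference
    direction, looking downstream (right-handed about the plane normal).
    The plane average is the perimeter-length-weighted mean of the field
    along the ring.
    """
    if len(ring.points) < n_points:
        raise ValueError(
            f"degenerate ring: {len(ring.points)} points, need >= {n_points}"
        )
    values = ring.values[field_name]
    closed_pts = np.vstack([ring.points, ring.points[:1]])
    seg_len = np.linalg.norm(np.diff(closed_pts, axis=0), axis=1)
    seg_mid = 0.5 * (closed_pts[:-1] + closed_pts[1:])
    centroid = (seg_mid * seg_len[:, None]).sum(axis=0) / seg_len.sum()

    e1 = spec.anterior_ref
    e2 = np.cross(spec.normal, e1)
    rel = ring.points - centroid
    theta = np.degrees(np.arctan2(rel @ e2, rel @ e1)) % 360.0

    order = np.argsort(theta)
    theta_sorted = theta[order]
    values_sorted = values[order]
    targets = np.arange(n_points) * (360.0 / n_points)
    samples = np.interp(targets, theta_sorted, values_sorted, period=360.0)

    closed_vals = np.append(values, values[0])
    plane_avg = float(
        np.sum(seg_len * 0.5 * (closed_vals[:-1] + closed_vals[1:])) / seg_len.sum()
    )
    return RingProfile(spec.label, targets, samples, plane_avg, ring.perimeter)


def group_stats(
    values_by_group: dict[str, list],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-group sample mean and standard deviation (n-1 denominator).

    Values may be scalars or arrays (e.g. the 8-point samples of a ring
    profile); statistics are taken pointwise across subjects.  With a single
    subject the standard deviation is NaN.
    """
    out = {}
    for group, values in values_by_group.items():
        if len(values) == 0:
            raise ValueError(f"group {group!r} is empty")
        arr = np.asarray(values, float)
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1) if len(values) > 1 else np.full_like(mean, np.nan)
        out[group] = (mean, sd)
    return out
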