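"""Wall-shear-stress metric fields over one cardiac cycle.

Given the wall-shear vector tau(t) at each vertex of a vessel surface over
one cycle of period T, the standard hemodynamic indices are

    TAWSS    = (1/T) int_0^T |tau| dt
    OSI      = 1/2 (1 - |int tau dt| / int |tau| dt),     in [0, 0.5]
    RRT      = 1 / ((1 - 2 OSI) TAWSS)                    = 1 / |mean vector|
    transWSS = (1/T) int |tau . (n x e_mean)| dt,
               e_mean = int tau dt / |int tau dt|

TAWSS measures shear magnitude, OSI the degree of direction reversal, RRT
near-wall residence time, and transWSS the cycle-averaged shear component
transverse (within the tangent plane) to the mean shear direction —
a multidirectionality measure that vanishes when the shear stays parallel
to one axis.

Two normalizations are provided: TAWSS (and instantaneous WSS) divided by
the time-averaged mean wall shear over an inlet band, and RRT divided by
its own area-weighted surface average.

Degenerate vertices (zero shear throughout, fully reversing shear, or an
undefined mean direction) receive NaN sentinels and are tracked in masks
rather than being clamped, so surface averages are not silently corrupted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import SurfaceMesh, surface_mean

__all__ = [
    "WSSVectorSeries",
    "MetricMaps",
    "tawss",
    "osi",
    "rrt",
    "transwss",
    "normalize_tawss",
    "compute_metrics",
]


@dataclass
class WSSVectorSeries:
    """Per-vertex wall-shear 3-vectors (Pa) over exactly one cycle.

    ``tau`` has shape (n_times, n_vertices, 3).  If the samples span less
    than the period, integrals close the cycle by wrapping the first sample.
    The vectors are expected to be tangent to the surface.
    """

    mesh: SurfaceMesh
    times: np.ndarray
    tau: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.tau = np.asarray(self.tau, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size < 4:
            raise ValueError("need at least 4 time samples")
        if self.tau.shape != (self.times.size, self.mesh.n_vertices, 3):
            raise ValueError(
                f"tau must have shape (n_times, n_vertices, 3) = "
                f"({self.times.size}, {self.mesh.n_vertices}, 3), got {self.tau.shape}"
            )
        if self.period <= 0 or self.times[-1] - self.times[0] > self.period * (1 + 1e-9):
            raise ValueError("samples must span at most one period")

    def closed_cycle(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and tau with the periodic sample wrapped to close the cycle."""
        span = self.times[-1] - self.times[0]
        if span >= self.period * (1 - 1e-9):
            return self.times, self.tau
        t = np.append(self.times, self.times[0] + self.period)
        tau = np.concatenate([self.tau, self.tau[:1]], axis=0)
        return t, tau

    def time_integral(self, values: np.ndarray, t: np.ndarray) -> np.ndarray:
        return np.trapezoid(values, t, axis=0)


@dataclass
class MetricMaps:
    """Per-vertex metric fields with sentinel masks for degenerate vertices."""

    tawss: np.ndarray  # Pa
    osi: np.ndarray  # dimensionless, NaN where undefined
    rrt: np.ndarray  # 1/Pa, NaN where infinite/undefined
    transwss: np.ndarray  # Pa, NaN where the mean direction is undefined
    tawss_n: np.ndarray | None = None
    rrt_n: np.ndarray | None = None
    inlet_mean_wss: float | None = None
    osi_undefined: np.ndarray | None = None  # mask: zero shear throughout
    rrt_infinite: np.ndarray | None = None  # mask: OSI = 0.5 exactly
    transwss_undefined: np.ndarray | None = None  # mask: |int tau dt| ~ 0


def _mean_vector_and_mag(s: WSSVectorSeries) -> tuple[np.ndarray, np.ndarray]:
    """(1/T) int tau dt per vertex, and (1/T) int |tau| dt."""
    t, tau = s.closed_cycle()
    mean_vec = s.time_integral(tau, t) / s.period
    mean_mag = s.time_integral(np.linalg.norm(tau, axis=2), t) / s.period
    return mean_vec, mean_mag


def tawss(s: WSSVectorSeries) -> np.ndarray:
    """Time-averaged wall-shear magnitude per vertex (Pa)."""
    t, tau = s.closed_cycle()
    return s.time_integral(np.linalg.norm(tau, axis=2), t) / s.period


def osi(s: WSSVectorSeries) -> tuple[np.ndarray, np.ndarray]:
    """Oscillatory shear index per vertex.

    Returns ``(osi, undefined_mask)``; vertices with zero shear throughout
    the cycle get NaN and are flagged in the mask.
    """
    mean_vec, mean_mag = _mean_vector_and_mag(s)
    undefined = mean_mag <= 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        val = 0.5 * (1.0 - np.linalg.norm(mean_vec, axis=1) / mean_mag)
    val = np.where(undefined, np.nan, val)
    # guard tiny negative round-off
    val = np.where(np.isfinite(val), np.clip(val, 0.0, 0.5), val)
    return val, undefined


def rrt(
    osi_field: np.ndarray, tawss_field: np.ndarray, mesh: SurfaceMesh | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Relative residence time RRT = 1/((1 - 2 OSI) TAWSS) and its normalization.

    Vertices where OSI = 0.5 (zero mean shear vector) have infinite RRT and
    receive NaN; they are excluded from the surface average used for RRTn.
    Returns ``(rrt, rrt_n, infinite_mask)``; ``rrt_n`` is None when no mesh
    is given.
    """
    denom = (1.0 - 2.0 * np.asarray(osi_field)) * np.asarray(tawss_field)
    infinite = ~(denom > 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(infinite, np.nan, 1.0 / denom)
    rrt_n = None
    if mesh is not None:
        rrt_n = val / surface_mean(val, mesh)
    return val, rrt_n, infinite


def transwss(s: WSSVectorSeries, rel_tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Transverse wall shear stress per vertex (Pa).

    The transverse direction at a vertex is n x e_mean with e_mean the unit
    mean-shear direction.  Vertices whose cycle-integral of tau is smaller
    than ``rel_tol`` times the maximum shear have no defined mean direction;
    they get NaN and are flagged in the returned mask.
    """
    t, tau = s.closed_cycle()
    int_tau = s.time_integral(tau, t)
    int_mag = np.linalg.norm(int_tau, axis=1)
    scale = np.max(np.linalg.norm(tau, axis=2), initial=0.0)
    undefined = int_mag <= rel_tol * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        e_mean = int_tau / int_mag[:, None]
    p = np.cross(s.mesh.vertex_normals, e_mean)
    proj = np.abs(np.einsum("tvk,vk->tv", tau, p))
    val = s.time_integral(proj, t) / s.period
    return np.where(undefined, np.nan, val), undefined


def normalize_tawss(
    tawss_field: np.ndarray,
    mesh: SurfaceMesh,
    inlet_band: str = "inlet_band",
    inlet_mean: float | None = None,
) -> tuple[np.ndarray, float]:
    """TAWSS divided by the mean wall shear over the inlet band.

    The normalizer is the area-weighted mean TAWSS over the ``inlet_band``
    region (time-averaged shear over an inlet-adjacent band of the vessel);
    the same normalizer applies to instantaneous WSS snapshots.  Returns the
    normalized field and the normalizer.
    """
    if inlet_mean is None:
        idx = mesh.region(inlet_band)
        if idx.size == 0:
            raise ValueError(f"inlet band {inlet_band!r} is empty")
        inlet_mean = surface_mean(tawss_field, mesh, idx)
    if inlet_mean <= 0:
        raise ValueError(f"inlet normalizer must be positive, got {inlet_mean}")
    return np.asarray(tawss_field) / inlet_mean, float(inlet_mean)


def compute_metrics(
    s: WSSVectorSeries, inlet_band: str | None = "inlet_band"
) -> MetricMaps:
    """All metric fields for one WSS vector series.

    ``inlet_band`` names the mesh region used to normalize TAWSS; pass None
    to skip both normalizations that need a region/mesh average.
    """
    ta = tawss(s)
    os_, os_mask = osi(s)
    rr, rr_n, rr_mask = rrt(os_, ta, s.mesh)
    tw, tw_mask = transwss(s)
    ta_n = None
    inlet_mean = None
    if inlet_band is not None and inlet_band in s.mesh.region_labels:
        ta_n, inlet_mean = normalize_tawss(ta, s.mesh, inlet_band)
    return MetricMaps(
        tawss=ta,
        osi=os_,
        rrt=rr,
        transwss=tw,
        tawss_n=ta_n,
        rrt_n=rr_n,
        inlet_mean_wss=inlet_mean,
        osi_undefined=os_mask,
        rrt_infinite=rr_mask,
        transwss_undefined=tw_mask,
    )
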