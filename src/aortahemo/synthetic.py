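"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here: aortic-like
one-cycle flow waveforms with prescribed mean/peak flow, cylindrical and
torus-arch surface meshes with analytic normals, per-vertex wall-shear
vector time series whose metric fields (TAWSS, OSI, RRT, transWSS) have
closed-form values, and the printed per-subject hemodynamic input table
used for regression tests.

All generators are deterministic under a fixed seed.  The waveform shape —
a half-sine systolic ejection over a fraction of the cycle on a low
diastolic plateau, optionally with a small early-diastolic reverse dip and
seeded harmonic jitter — emulates the gross morphology of PC-MRI aortic
root waveforms, not any individual patient trace.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ellipe

from .mesh import SurfaceMesh
from .pulsatile import WomersleyProblem, analytic_wall_shear
from .regional import CenterlineTrack
from .waveform import FlowWaveform
from .wss import MetricMaps, WSSVectorSeries

__all__ = [
    "WaveformTemplate",
    "SyntheticWSSSpec",
    "make_waveform",
    "make_cylinder_mesh",
    "make_torus_arch",
    "make_wss_series",
    "make_subject_table",
    "make_ts_biometrics",
    "save_wss_series",
]


@dataclass(frozen=True)
class WaveformTemplate:
    """Target shape parameters for a synthetic aortic flow waveform (ml/s, s)."""

    T: float
    Qmean: float
    Qpeak: float
    systolic_fraction: float = 0.35
    reverse_amplitude: float = 0.0
    jitter_amplitude: float = 0.0  # fraction of Qpeak, keep <= 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.Qpeak > self.Qmean > 0):
            raise ValueError("need Qpeak > Qmean > 0")
        if not (0 < self.systolic_fraction < 1):
            raise ValueError("systolic fraction must lie in (0, 1)")
        if self.reverse_amplitude < 0 or self.jitter_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")


def make_waveform(t: WaveformTemplate, n_samples: int = 100) -> FlowWaveform:
    """Synthesize a one-cycle waveform hitting the template's Qmean and Qpeak.

    Systole is a half-sine of duration ``systolic_fraction * T``; diastole a
    constant plateau, optionally dented by a half-sine reverse dip over the
    first tenth of the cycle after end-systole.  Amplitude and plateau are
    solved in closed form so the continuous cycle mean equals Qmean and the
    maximum equals Qpeak; the realized (sampled) statistics agree within
    quadrature error.  Seeded harmonic jitter adds zero-mean perturbation.
    """
    ts = t.systolic_fraction * t.T
    dip_frac = 0.1
    # peak: d + a = Qpeak ; mean: d + a*(2/pi)*sf - r*(2/pi)*dip_frac = Qmean
    denom = 1.0 - (2.0 / math.pi) * t.systolic_fraction
    a = (t.Qpeak - t.Qmean - t.reverse_amplitude * (2.0 / math.pi) * dip_frac) / denom
    d = t.Qpeak - a
    if a <= 0 or d < -t.reverse_amplitude:
        raise ValueError(
            f"infeasible target pair (Qmean={t.Qmean}, Qpeak={t.Qpeak}) "
            f"for systolic fraction {t.systolic_fraction}"
        )
    times = t.T * np.arange(n_samples) / n_samples
    q = np.full(n_samples, d)
    sys_mask = times < ts
    q[sys_mask] = d + a * np.sin(math.pi * times[sys_mask] / ts)
    if t.reverse_amplitude > 0:
        dip = (times >= ts) & (times < ts + dip_frac * t.T)
        q[dip] -= t.reverse_amplitude * np.sin(math.pi * (times[dip] - ts) / (dip_frac * t.T))
    if t.jitter_amplitude > 0:
        rng = np.random.default_rng(t.seed)
        for k in range(2, 6):
            amp = t.jitter_amplitude * t.Qpeak * rng.uniform(-1, 1) / k
            q += amp * np.sin(2.0 * math.pi * k * times / t.T + rng.uniform(0, 2 * math.pi))
    return FlowWaveform.from_ml_s(times, q, t.T)


def make_cylinder_mesh(
    radius_mm: float,
    length_mm: float,
    n_theta: int = 32,
    n_z: int = 17,
    inlet_band_mm: float | None = None,
) -> SurfaceMesh:
    """Open lateral surface of a circular cylinder along +z with analytic normals.

    The ``inlet_band`` region holds vertices within ``inlet_band_mm`` of the
    z = 0 (inlet) end; the default band width is one tenth of the diameter.
    """
    if inlet_band_mm is None:
        inlet_band_mm = 0.2 * radius_mm  # 0.1 * D
    theta = 2.0 * math.pi * np.arange(n_theta) / n_theta
    z = np.linspace(0.0, length_mm, n_z)
    tt, zz = np.meshgrid(theta, z)
    verts = np.column_stack(
        [radius_mm * np.cos(tt).ravel(), radius_mm * np.sin(tt).ravel(), zz.ravel()]
    )
    normals = np.column_stack(
        [np.cos(tt).ravel(), np.sin(tt).ravel(), np.zeros(tt.size)]
    )
    tris = []
    for iz in range(n_z - 1):
        for it in range(n_theta):
            a = iz * n_theta + it
            b = iz * n_theta + (it + 1) % n_theta
            c = a + n_theta
            e = b + n_theta
            tris.append([a, b, e])
            tris.append([a, e, c])
    inlet = np.nonzero(verts[:, 2] <= inlet_band_mm + 1e-9)[0]
    return SurfaceMesh(verts, np.array(tris), normals, {"inlet_band": inlet})


def cylinder_axial_tangents(mesh: SurfaceMesh) -> np.ndarray:
    """Unit axial (z) tangent at each vertex of a cylinder mesh."""
    t = np.zeros_like(mesh.vertices)
    t[:, 2] = 1.0
    return t


def make_torus_arch(
    arch_radius_mm: float = 40.0,
    tube_radius_mm: float = 5.0,
    span_deg: float = 180.0,
    n_u: int = 33,
    n_v: int = 24,
) -> tuple[SurfaceMesh, CenterlineTrack, np.ndarray]:
    """Curved-tube (torus segment) stand-in for an aortic arch.

    The tube centerline is a circular arc of radius ``arch_radius_mm`` in the
    x-z plane; ``span_deg`` degrees are swept.  Returns the surface mesh, the
    centerline with landmarks placed at fixed arc fractions (``inlet`` 0,
    ``BCA`` 0.32, ``LCCA`` 0.44, ``LSA`` 0.56 of the arc), and the per-vertex
    unit downstream tangent.  A geometric fixture only — no anatomical
    fidelity is claimed.
    """
    span = math.radians(span_deg)
    u = span * np.arange(n_u) / (n_u - 1)
    v = 2.0 * math.pi * np.arange(n_v) / n_v
    uu, vv = np.meshgrid(u, v, indexing="ij")
    er = np.stack([np.sin(uu), np.zeros_like(uu), np.cos(uu)], axis=-1)  # radial
    ey = np.zeros_like(er)
    ey[..., 1] = 1.0
    center = arch_radius_mm * er
    normal = np.cos(vv)[..., None] * er + np.sin(vv)[..., None] * ey
    verts = (center + tube_radius_mm * normal).reshape(-1, 3)
    normals = normal.reshape(-1, 3)
    tangent = np.stack([np.cos(uu), np.zeros_like(uu), -np.sin(uu)], axis=-1).reshape(-1, 3)

    tris = []
    for iu in range(n_u - 1):
        for iv in range(n_v):
            a = iu * n_v + iv
            b = iu * n_v + (iv + 1) % n_v
            c = a + n_v
            e = b + n_v
            tris.append([a, b, e])
            tris.append([a, e, c])
    mesh = SurfaceMesh(verts, np.array(tris), normals)

    cl_pts = arch_radius_mm * np.stack([np.sin(u), np.zeros_like(u), np.cos(u)], axis=-1)
    arc_len = arch_radius_mm * span
    landmarks = {
        "inlet": 0.0,
        "BCA": 0.32 * arc_len,
        "LCCA": 0.44 * arc_len,
        "LSA": 0.56 * arc_len,
    }
    return mesh, CenterlineTrack(cl_pts, landmarks), tangent


@dataclass(frozen=True)
class SyntheticWSSSpec:
    """Recipe for a wall-shear vector series with closed-form metric values.

    Recipes (all shears in Pa, directions in the local tangent plane):

    - ``constant``: tau = mean * axial
    - ``uniaxial``: tau = (mean + amplitude sin(2 pi t/T)) * axial
    - ``biaxial``:  tau = mean * axial + amplitude sin(2 pi t/T) * circumferential
    - ``womersley``: tau(t) from the analytic Womersley wall shear of
      ``problem``, axial, uniform over the lateral surface
    """

    recipe: str = "constant"
    mesh_kind: str = "cylinder"
    radius_mm: float = 10.0
    length_mm: float = 60.0
    mean_pa: float = 1.0
    amplitude_pa: float = 0.0
    period_s: float = 1.0
    problem: WomersleyProblem | None = None
    n_time: int = 100
    n_theta: int = 32
    n_z: int = 17
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recipe not in ("constant", "uniaxial", "biaxial", "womersley"):
            raise ValueError(f"unknown recipe {self.recipe!r}")
        if self.mesh_kind not in ("cylinder", "torus"):
            raise ValueError(f"unknown mesh kind {self.mesh_kind!r}")
        if self.recipe == "womersley" and self.problem is None:
            raise ValueError("womersley recipe needs a WomersleyProblem")


def _uniaxial_tawss(mean: float, amp: float) -> float:
    """Closed-form cycle mean of |mean + amp sin(theta)|."""
    m, a = abs(mean), abs(amp)
    if a <= m:
        return m
    return (2.0 / math.pi) * (math.sqrt(a**2 - m**2) + m * math.asin(m / a))


def make_wss_series(spec: SyntheticWSSSpec) -> tuple[WSSVectorSeries, MetricMaps]:
    """Generate a WSS vector series and its exact expected metric fields.

    The ground-truth :class:`MetricMaps` holds the closed-form per-vertex
    values implied by the recipe (uniform over the surface), so tests can
    compare pipeline output against values that were never computed by the
    pipeline itself.
    """
    if spec.mesh_kind == "cylinder":
        mesh = make_cylinder_mesh(spec.radius_mm, spec.length_mm, spec.n_theta, spec.n_z)
        axial = cylinder_axial_tangents(mesh)
    else:
        mesh, _, axial = make_torus_arch(
            tube_radius_mm=spec.radius_mm, n_u=spec.n_z, n_v=spec.n_theta
        )
    circ = np.cross(mesh.vertex_normals, axial)
    times = spec.period_s * np.arange(spec.n_time) / spec.n_time
    omega = 2.0 * math.pi / spec.period_s
    V = mesh.n_vertices
    m, a = spec.mean_pa, spec.amplitude_pa

    if spec.recipe == "constant":
        tau = np.broadcast_to(m * axial, (spec.n_time, V, 3)).copy()
        gt = dict(tawss=m, osi=0.0, rrt=1.0 / m, transwss=0.0)
    elif spec.recipe == "uniaxial":
        s = m + a * np.sin(omega * times)
        tau = s[:, None, None] * axial[None, :, :]
        ta = _uniaxial_tawss(m, a)
        mean_mag = abs(m)
        gt = dict(
            tawss=ta,
            osi=0.5 * (1.0 - mean_mag / ta),
            rrt=np.inf if mean_mag == 0 else 1.0 / mean_mag,
            transwss=0.0 if mean_mag > 0 else np.nan,
        )
    elif spec.recipe == "biaxial":
        s = a * np.sin(omega * times)
        tau = m * axial[None, :, :] + s[:, None, None] * circ[None, :, :]
        ta = (2.0 / math.pi) * math.sqrt(m**2 + a**2) * ellipe(a**2 / (m**2 + a**2))
        gt = dict(
            tawss=ta,
            osi=0.5 * (1.0 - abs(m) / ta),
            rrt=1.0 / abs(m),
            transwss=2.0 * abs(a) / math.pi,
        )
    else:  # womersley
        prob = spec.problem
        times = prob.period * np.arange(spec.n_time) / spec.n_time
        shear = analytic_wall_shear(prob, times).tau
        tau = shear[:, None, None] * axial[None, :, :]
        # dense-quadrature reference from the same analytic series (20x grid)
        t_dense = prob.period * np.arange(20 * spec.n_time) / (20 * spec.n_time)
        s_dense = analytic_wall_shear(prob, t_dense).tau
        ta = float(np.mean(np.abs(s_dense)))
        mean_mag = abs(float(np.mean(s_dense)))
        gt = dict(
            tawss=ta,
            osi=0.5 * (1.0 - mean_mag / ta),
            rrt=np.inf if mean_mag == 0 else 1.0 / mean_mag,
            transwss=0.0 if mean_mag > 0 else np.nan,
        )

    ones = np.ones(V)
    period = spec.problem.period if spec.recipe == "womersley" else spec.period_s
    series = WSSVectorSeries(mesh, times, tau, period)
    truth = MetricMaps(
        tawss=gt["tawss"] * ones,
        osi=gt["osi"] * ones,
        rrt=gt["rrt"] * ones,
        transwss=gt["transwss"] * ones,
        tawss_n=ones.copy(),  # uniform field: inlet normalization is identity
        rrt_n=ones.copy() if np.isfinite(gt["rrt"]) else None,
        inlet_mean_wss=gt["tawss"],
    )
    return series, truth


_SUBJECTS = [
    # subject, group, D (mm), T (s), Qmean (ml/s), Qpeak (ml/s)
    ("H1", "healthy", 17.53, 0.57, 48.0, 197.0),
    ("H2", "healthy", 22.48, 1.00, 82.0, 302.0),
    ("H3", "healthy", 19.68, 0.76, 56.0, 223.0),
    ("TS1", "TS", 33.77, 0.68, 77.0, 254.0),
    ("TS2", "TS", 19.30, 0.57, 90.0, 294.0),
    ("TS3", "TS", 22.56, 0.71, 83.0, 320.0),
    ("TS4", "TS", 18.99, 0.72, 56.0, 207.0),
]

_TS_BIOMETRICS = [
    # subject, age (y), height (cm), weight (kg), BP sys/dia (mmHg)
    ("TS1", 14, 136.60, 47.85, 116, 75),
    ("TS2", 10, 134.70, 44.15, 102, 61),
    ("TS3", 14, 143.70, 60.20, 104, 43),
    ("TS4", 13, 138.30, 33.00, 111, 69),
]


def make_subject_table() -> pd.DataFrame:
    """Per-subject hemodynamic inputs (inlet diameter, period, mean/peak flow)
    for the three healthy and four Turner syndrome girls of the study cohort."""
    return pd.DataFrame(
        _SUBJECTS, columns=["subject", "group", "D_mm", "T_s", "Qmean_ml_s", "Qpeak_ml_s"]
    )


def make_ts_biometrics() -> pd.DataFrame:
    """Biometrics of the four Turner syndrome girls (height, weight, BP)."""
    return pd.DataFrame(
        _TS_BIOMETRICS,
        columns=["subject", "age_y", "height_cm", "weight_kg", "bp_sys", "bp_dia"],
    )


def save_wss_series(
    out_dir: str | Path, series: WSSVectorSeries, truth: MetricMaps | None = None
) -> Path:
    """Write a WSS series as a .vtp file sequence with a .pvd index.

    The per-time shear vectors go into files ``wss_####.vtp`` (array
    ``wss_pa``); the closed-form ground-truth metrics, when given, go into a
    sidecar ``ground_truth.json`` so tests never re-derive expected values.
    Returns the path of the .pvd index.
    """
    from .vtkio import write_pvd, write_vtp

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, t in enumerate(series.times):
        name = f"wss_{i:04d}.vtp"
        write_vtp(out / name, series.mesh, {"wss_pa": series.tau[i]})
        entries.append((name, float(t)))
    pvd = out / "series.pvd"
    write_pvd(pvd, entries)
    if truth is not None:
        gt = {
            "tawss": truth.tawss.tolist(),
            "osi": truth.osi.tolist(),
            "rrt": truth.rrt.tolist(),
            "transwss": truth.transwss.tolist(),
            "period": series.period,
        }
        (out / "ground_truth.json").write_text(json.dumps(gt))
    return pvd
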