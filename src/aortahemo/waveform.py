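"""One-cycle volumetric flow waveforms and subject biometrics.

A :class:`FlowWaveform` carries one cardiac cycle of volumetric flow at the
aortic root, the kind of trace produced by through-plane PC-MRI
segmentation.  Flow is stored internally in m^3/s; file I/O and reported
statistics use ml/s, the unit clinical tables print.

The module derives per-subject statistics (mean/peak flow, heart rate,
cardiac output, the three analysis time points of the cardiac cycle),
normalizes waveforms by mean flow and period, and averages normalized
waveforms across a subject group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

ML_S_TO_M3_S = 1e-6

__all__ = [
    "FlowWaveform",
    "WaveformStats",
    "Biometrics",
    "load_waveform",
    "save_waveform",
    "waveform_stats",
    "normalize_waveform",
    "group_average",
    "bmi",
    "bsa",
]


@dataclass
class FlowWaveform:
    """Volumetric flow over exactly one cardiac cycle.

    Parameters
    ----------
    times : array
        Sample times in seconds, strictly increasing, spanning at most one
        period.  If the last sample falls short of ``times[0] + period`` the
        cycle is treated as periodic and integrals wrap the first sample to
        close it.
    flow : array
        Volumetric flow in m^3/s (use :meth:`from_ml_s` for clinical units).
        Dimensionless after :func:`normalize_waveform`.
    period : float
        Cardiac cycle period T in seconds.
    """

    times: np.ndarray
    flow: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.times.ndim != 1 or self.flow.shape != self.times.shape:
            raise ValueError("times and flow must be 1-D arrays of equal length")
        if self.times.size < 8:
            raise ValueError(f"waveform needs >= 8 samples, got {self.times.size}")
        if np.any(np.isnan(self.times)) or np.any(np.isnan(self.flow)):
            raise ValueError("waveform contains NaN entries")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("non-monotone time column")
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")
        span = self.times[-1] - self.times[0]
        if span > self.period * (1 + 1e-9):
            raise ValueError(
                f"samples span {span:.6g} s, longer than the period {self.period:.6g} s"
            )

    @classmethod
    def from_ml_s(cls, times: Sequence[float], flow_ml_s: Sequence[float], period: float) -> "FlowWaveform":
        return cls(np.asarray(times, float), np.asarray(flow_ml_s, float) * ML_S_TO_M3_S, period)

    @property
    def flow_ml_s(self) -> np.ndarray:
        return self.flow / ML_S_TO_M3_S

    def closed_cycle(self) -> tuple[np.ndarray, np.ndarray]:
        """Times/flow with the cycle wrapped shut (last point = first point at t0+T)."""
        span = self.times[-1] - self.times[0]
        if span >= self.period * (1 - 1e-9):
            return self.times, self.flow
        t = np.append(self.times, self.times[0] + self.period)
        q = np.append(self.flow, self.flow[0])
        return t, q

    def cycle_mean(self) -> float:
        """Cycle-averaged flow (same unit as ``flow``), trapezoid with wrap closure."""
        t, q = self.closed_cycle()
        return float(np.trapezoid(q, t) / self.period)


@dataclass(frozen=True)
class WaveformStats:
    """Scalar statistics of one waveform.

    Flow statistics are reported in ml/s, cardiac output in l/min, heart
    rate in beats per minute and the three analysis time points in seconds:
    ``t_peak`` (peak systole), ``t_maxdecel`` (maximum deceleration, the
    minimum of dU/dt), ``t_middiastole`` (mid-diastole).  ``peak_decel`` is
    the minimum rate of change of the section-mean velocity, in m/s^2
    (negative during deceleration).
    """

    Qmean: float
    Qpeak: float
    HR: float
    CO: float
    t_peak: float
    t_maxdecel: float
    t_middiastole: float
    peak_decel: float


@dataclass(frozen=True)
class Biometrics:
    """Subject biometrics; blood pressures are carried through unchanged."""

    height_cm: float
    weight_kg: float
    age_years: float | None = None
    bp_systolic: float | None = None
    bp_diastolic: float | None = None

    def __post_init__(self) -> None:
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise ValueError("height and weight must be positive")


def load_waveform(path: str | Path, period: float, flow_unit: str = "ml/s") -> FlowWaveform:
    """Read a two-column (time, flow) table into a validated waveform.

    The file must have at least two numeric columns: time in seconds and
    flow in ``flow_unit`` (``"ml/s"`` or ``"m3/s"``).  A header row is
    optional.
    """
    df = pd.read_csv(path)
    # tolerate headerless files
    try:
        float(df.columns[0])
    except (TypeError, ValueError):
        pass
    else:
        df = pd.read_csv(path, header=None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected >= 2 numeric columns, got {df.shape[1]}")
    times = df.iloc[:, 0].to_numpy(float)
    flow = df.iloc[:, 1].to_numpy(float)
    if flow_unit == "ml/s":
        flow = flow * ML_S_TO_M3_S
    elif flow_unit != "m3/s":
        raise ValueError(f"unknown flow unit {flow_unit!r}")
    return FlowWaveform(times, flow, period)


def save_waveform(w: FlowWaveform, path: str | Path) -> None:
    """Write a waveform as CSV with header ``time_s,flow_ml_s``."""
    pd.DataFrame({"time_s": w.times, "flow_ml_s": w.flow_ml_s}).to_csv(path, index=False)


def _end_systole(w: FlowWaveform, i_peak: int) -> float:
    """End of systole: first post-peak zero crossing of Q, else first local minimum."""
    q = w.flow
    t = w.times
    for i in range(i_peak + 1, q.size):
        if q[i] < 0.0:  # flow reversal: interpolate the crossing
            f = q[i - 1] / (q[i - 1] - q[i])
            return float(t[i - 1] + f * (t[i] - t[i - 1]))
    for i in range(i_peak + 1, q.size - 1):
        if q[i] <= q[i - 1] and q[i] <= q[i + 1]:
            return float(t[i])
    return float(t[-1])


def waveform_stats(
    w: FlowWaveform,
    D_mm: float,
    smooth: bool = False,
    middiastole_fraction: float = 0.5,
) -> WaveformStats:
    """Derive the scalar statistics of one waveform.

    Parameters
    ----------
    D_mm : float
        Inlet diameter in mm, used to convert flow to section-mean velocity
        U = Q/(pi D^2/4) for the deceleration analysis.
    smooth : bool
        Apply a local-polynomial (Savitzky-Golay, window 5, degree 2)
        smoothing to the velocity before differentiating.  Off by default.
    middiastole_fraction : float
        Position of mid-diastole between end-systole and cycle end
        (0.5 = midpoint).
    """
    if D_mm <= 0:
        raise ValueError(f"diameter must be positive, got {D_mm}")
    qmean = w.cycle_mean()  # m^3/s
    qpeak = float(w.flow.max())
    hr = 60.0 / w.period
    co = qmean / ML_S_TO_M3_S * 0.06  # ml/s -> l/min

    area = np.pi * (D_mm * 1e-3) ** 2 / 4.0
    u = w.flow / area
    if smooth and u.size >= 5:
        u = savgol_filter(u, window_length=5, polyorder=2)
    dudt = np.gradient(u, w.times)
    i_peak = int(np.argmax(w.flow))
    i_decel = int(np.argmin(dudt))
    t_es = _end_systole(w, i_peak)
    t_end = w.times[0] + w.period
    t_mid = t_es + middiastole_fraction * (t_end - t_es)
    return WaveformStats(
        Qmean=qmean / ML_S_TO_M3_S,
        Qpeak=qpeak / ML_S_TO_M3_S,
        HR=hr,
        CO=co,
        t_peak=float(w.times[i_peak]),
        t_maxdecel=float(w.times[i_decel]),
        t_middiastole=float(t_mid),
        peak_decel=float(dudt.min()),
    )


def normalize_waveform(w: FlowWaveform, stats: WaveformStats | None = None) -> FlowWaveform:
    """Normalize flow by the cycle-mean flow and time by the period.

    Returns a dimensionless waveform with t* in [0, 1) and unit mean; its
    ``flow`` array is Q/Qmean, not a volumetric flow.
    """
    qmean = stats.Qmean * ML_S_TO_M3_S if stats is not None else w.cycle_mean()
    if qmean <= 0:
        raise ValueError(f"mean flow must be positive to normalize, got {qmean}")
    tstar = (w.times - w.times[0]) / w.period
    return FlowWaveform(tstar, w.flow / qmean, 1.0)


def group_average(waveforms: Iterable[FlowWaveform], n_points: int = 100) -> FlowWaveform:
    """Pointwise mean of normalized waveforms on a common uniform t* grid.

    Each waveform is resampled by periodic linear interpolation onto
    ``n_points`` equispaced points of the unit cycle.
    """
    ws = list(waveforms)
    if not ws:
        raise ValueError("group_average needs at least one waveform")
    grid = np.linspace(0.0, 1.0, n_points, endpoint=False)
    resampled = []
    for w in ws:
        tstar = (w.times - w.times[0]) / w.period
        resampled.append(np.interp(grid, tstar, w.flow, period=1.0))
    return FlowWaveform(grid, np.mean(resampled, axis=0), 1.0)


def bmi(b: Biometrics) -> float:
    """Body mass index, kg/m^2."""
    return b.weight_kg / (b.height_cm / 100.0) ** 2


def bsa(b: Biometrics, formula: str = "dubois") -> float:
    """Body surface area in m^2.

    ``"dubois"`` (default): 0.007184 * h^0.725 * w^0.425 with h in cm, w in
    kg.  ``"mosteller"``: sqrt(h * w / 3600).
    """
    if formula == "dubois":
        return 0.007184 * b.height_cm**0.725 * b.weight_kg**0.425
    if formula == "mosteller":
        return float(np.sqrt(b.height_cm * b.weight_kg / 3600.0))
    raise ValueError(f"unknown BSA formula {formula!r}")
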