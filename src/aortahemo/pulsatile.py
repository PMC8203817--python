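"""Pulsatile flow in a rigid circular pipe: analytic Womersley solution and a
finite-difference companion solver.

The axisymmetric, fully developed reduction of the incompressible
Navier-Stokes equations for axial velocity u(r, t) driven by an oscillatory
pressure gradient is

    rho du/dt = G(t) + mu (d2u/dr2 + (1/r) du/dr),    u(R, t) = 0,

with G(t) = -dp/dx = sum_k Re{A_k exp(i w_k t)}.  The steady component
(w = 0, A_0 real) gives Poiseuille flow; each oscillatory harmonic has the
classical Bessel-function solution

    u_k(r, t) = Re{ (A_k / (i rho w_k)) [1 - J0(z r/R)/J0(z)] e^{i w_k t} },
    z = i^{3/2} alpha_k,   alpha_k = R sqrt(w_k rho / mu),

where alpha_k is the per-harmonic Womersley number.  The finite-difference
path integrates the same equation with a Crank-Nicolson scheme from rest
until time-periodicity, mirroring the transient-to-periodic protocol of a
full 3-D simulation, and reports how periodic the final cycle is.

This 1-D problem is the desk-scale validation path for the wall-shear
metric machinery: it produces wall-shear time series with known closed-form
behavior (Poiseuille force balance, quasi-steady and high-frequency
asymptotics) against which both solvers and the downstream metrics can be
checked.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import jv

from .fluids import BLOOD, FluidProperties
from .waveform import FlowWaveform

__all__ = [
    "WomersleyProblem",
    "VelocityField1D",
    "WallShearSeries",
    "womersley_analytic",
    "womersley_fd",
    "wall_shear",
    "analytic_wall_shear",
    "analytic_flow",
    "fit_harmonics",
]

I_3_2 = cmath.exp(1j * 3.0 * math.pi / 4.0)  # i^(3/2)


@dataclass(frozen=True)
class WomersleyProblem:
    """Harmonic specification of the driving pressure gradient.

    Parameters
    ----------
    R : float
        Pipe radius in m.
    harmonics : sequence of (omega, A)
        Angular frequency in rad/s and complex amplitude of -dp/dx in Pa/m.
        ``omega = 0`` is the steady component (real amplitude).
    fluid : FluidProperties
    period : float, optional
        Cycle period in s.  Defaults to 2*pi over the smallest nonzero
        frequency, or 1.0 for a steady-only problem.
    """

    R: float
    harmonics: tuple[tuple[float, complex], ...]
    fluid: FluidProperties = BLOOD
    period: float | None = None

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"radius must be positive, got {self.R}")
        hs = tuple((float(w), complex(a)) for w, a in self.harmonics)
        object.__setattr__(self, "harmonics", hs)
        freqs = [w for w, _ in hs]
        if any(w < 0 for w in freqs):
            raise ValueError("angular frequencies must be non-negative")
        if len(set(freqs)) != len(freqs):
            raise ValueError("harmonic frequencies must be distinct")
        if self.period is None:
            nonzero = [w for w in freqs if w > 0]
            object.__setattr__(
                self, "period", 2.0 * math.pi / min(nonzero) if nonzero else 1.0
            )

    def alpha(self, omega: float) -> float:
        """Womersley number of one harmonic, R * sqrt(omega rho / mu)."""
        return self.R * math.sqrt(omega * self.fluid.rho / self.fluid.mu)

    def gradient(self, t: np.ndarray) -> np.ndarray:
        """G(t) = -dp/dx in Pa/m at the given times."""
        t = np.asarray(t, float)
        g = np.zeros_like(t)
        for w, a in self.harmonics:
            g = g + (a * np.exp(1j * w * t)).real
        return g


@dataclass
class VelocityField1D:
    """Axial velocity u(r, t) on a radius x time grid over one cycle."""

    radii: np.ndarray
    times: np.ndarray
    u: np.ndarray  # shape (len(radii), len(times))
    periodicity: float | None = None  # relative L2 change between last two cycles

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, float)
        self.times = np.asarray(self.times, float)
        self.u = np.asarray(self.u, float)
        if self.u.shape != (self.radii.size, self.times.size):
            raise ValueError("u must have shape (n_radii, n_times)")


@dataclass
class WallShearSeries:
    """Scalar wall shear tau(t) in Pa, positive when the flow is in +x."""

    times: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.tau = np.asarray(self.tau, float)
        if self.tau.shape != self.times.shape:
            raise ValueError("times and tau must have the same length")


def _harmonic_profile(p: WomersleyProblem, omega: float, A: complex, radii: np.ndarray) -> np.ndarray:
    """Complex radial profile of one oscillatory harmonic."""
    alpha = p.alpha(omega)
    z = I_3_2 * alpha
    j0z = jv(0, z)
    prof = (A / (1j * p.fluid.rho * omega)) * (1.0 - jv(0, z * radii / p.R) / j0z)
    if not np.all(np.isfinite(prof)):
        raise FloatingPointError(
            f"Bessel evaluation failed for alpha={alpha:.3g}; "
            "the harmonic is outside the representable range"
        )
    return prof


def womersley_analytic(p: WomersleyProblem, radii: np.ndarray, times: np.ndarray) -> VelocityField1D:
    """Evaluate the closed-form Womersley velocity field on a grid."""
    radii = np.asarray(radii, float)
    times = np.asarray(times, float)
    u = np.zeros((radii.size, times.size))
    for omega, A in p.harmonics:
        if omega == 0.0:
            u += (A.real * (p.R**2 - radii**2) / (4.0 * p.fluid.mu))[:, None]
        else:
            prof = _harmonic_profile(p, omega, A, radii)
            u += (prof[:, None] * np.exp(1j * omega * times)[None, :]).real
    return VelocityField1D(radii, times, u)


def analytic_wall_shear(p: WomersleyProblem, times: np.ndarray) -> WallShearSeries:
    """Exact wall shear tau(t) = -mu du/dr|_{r=R} from the Bessel series."""
    times = np.asarray(times, float)
    tau = np.zeros_like(times)
    for omega, A in p.harmonics:
        if omega == 0.0:
            tau += A.real * p.R / 2.0
        else:
            z = I_3_2 * p.alpha(omega)
            c = A / (1j * p.fluid.rho * omega)
            tau_c = -p.fluid.mu * c * (z / p.R) * jv(1, z) / jv(0, z)
            tau += (tau_c * np.exp(1j * omega * times)).real
    return WallShearSeries(times, tau)


def analytic_flow(p: WomersleyProblem, times: np.ndarray) -> np.ndarray:
    """Volumetric flow Q(t) in m^3/s implied by the problem's harmonics."""
    times = np.asarray(times, float)
    q = np.zeros_like(times)
    area = math.pi * p.R**2
    for omega, A in p.harmonics:
        if omega == 0.0:
            q += A.real * area * p.R**2 / (8.0 * p.fluid.mu)
        else:
            z = I_3_2 * p.alpha(omega)
            f10 = 2.0 * jv(1, z) / (z * jv(0, z))
            q_c = (A / (1j * p.fluid.rho * omega)) * area * (1.0 - f10)
            q += (q_c * np.exp(1j * omega * times)).real
    return q


def _laplacian_diagonals(nr: int, dr: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tridiagonal cylindrical Laplacian on r_j = j dr, j = 0..nr-1 (u_nr = 0).

    Row 0 uses the axis limit d2u/dr2 + (1/r) du/dr -> 2 d2u/dr2 with the
    symmetry image u_{-1} = u_1.
    """
    j = np.arange(1, nr)
    lower = np.zeros(nr)
    diag = np.zeros(nr)
    upper = np.zeros(nr)
    diag[0] = -4.0 / dr**2
    upper[0] = 4.0 / dr**2
    diag[1:] = -2.0 / dr**2
    lower[1:] = (1.0 - 0.5 / j) / dr**2
    upper[1:] = (1.0 + 0.5 / j) / dr**2
    return lower, diag, upper


def womersley_fd(
    p: WomersleyProblem,
    nr: int = 64,
    steps_per_cycle: int = 200,
    n_cycles: int = 5,
) -> VelocityField1D:
    """Crank-Nicolson solution of the reduced momentum equation from rest.

    Integrates ``n_cycles`` cardiac cycles (default 5, after which a full
    3-D simulation of this kind is conventionally taken as time-periodic)
    and returns the final cycle, with the relative L2 change between the
    last two cycles stored as ``periodicity``.

    Parameters
    ----------
    nr : int
        Radial intervals (>= 16); the grid has nr+1 nodes from axis to wall.
    steps_per_cycle : int
        Time steps per cycle (>= 50 per period of the highest harmonic).
    """
    if nr < 16:
        raise ValueError(f"nr must be >= 16, got {nr}")
    T = p.period
    dt = T / steps_per_cycle
    w_max = max((w for w, _ in p.harmonics), default=0.0)
    if w_max > 0 and (2.0 * math.pi / w_max) / dt < 50.0 * (1 - 1e-9):
        raise ValueError(
            "time step too coarse: need >= 50 steps per period of the highest harmonic"
        )
    nu = p.fluid.nu
    dr = p.R / nr
    lower, diag, upper = _laplacian_diagonals(nr, dr)

    # Banded LHS matrix  I - (nu dt / 2) L
    c = 0.5 * nu * dt
    ab = np.zeros((3, nr))
    ab[0, 1:] = -c * upper[:-1]
    ab[1, :] = 1.0 - c * diag
    ab[2, :-1] = -c * lower[1:]

    def apply_rhs(u: np.ndarray) -> np.ndarray:
        out = (1.0 + c * diag) * u
        out[:-1] += c * upper[:-1] * u[1:]
        out[1:] += c * lower[1:] * u[:-1]
        return out

    u = np.zeros(nr)  # start from rest
    n_steps = n_cycles * steps_per_cycle
    prev_cycle = np.zeros((steps_per_cycle, nr))
    last_cycle = np.zeros((steps_per_cycle, nr))
    for n in range(n_steps):
        t_mid = (n + 0.5) * dt
        rhs = apply_rhs(u) + (dt / p.fluid.rho) * p.gradient(t_mid)
        u = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(u)):
            raise FloatingPointError(
                f"finite-difference solution diverged at step {n} "
                f"(nr={nr}, dt={dt:.3g}); refine the grid or time step"
            )
        cyc, pos = divmod(n, steps_per_cycle)
        if cyc == n_cycles - 1:
            last_cycle[pos] = u
        elif cyc == n_cycles - 2:
            prev_cycle[pos] = u

    norm = np.linalg.norm(last_cycle)
    periodicity = (
        float(np.linalg.norm(last_cycle - prev_cycle) / norm) if norm > 0 else 0.0
    )
    # final cycle sampled at phases dt..T (step endpoints), wall node appended
    times = dt * (1.0 + np.arange(steps_per_cycle))
    radii = dr * np.arange(nr + 1)
    u_full = np.vstack([last_cycle.T, np.zeros(steps_per_cycle)])
    return VelocityField1D(radii, times, u_full, periodicity=periodicity)


def wall_shear(v: VelocityField1D, fluid: FluidProperties = BLOOD) -> WallShearSeries:
    """Wall shear from a velocity field by one-sided second-order differencing.

    tau(t) = -mu du/dr at r = R, positive for flow in +x.  Requires at least
    3 radial nodes and assumes the last node is the (no-slip) wall.
    """
    if v.radii.size < 3:
        raise ValueError("need at least 3 radial nodes for a one-sided stencil")
    dr = v.radii[-1] - v.radii[-2]
    if not math.isclose(dr, v.radii[-2] - v.radii[-3], rel_tol=1e-6):
        raise ValueError("wall_shear expects a uniform radial grid near the wall")
    dudr = (3.0 * v.u[-1] - 4.0 * v.u[-2] + v.u[-3]) / (2.0 * dr)
    return WallShearSeries(v.times, -fluid.mu * dudr)


def fit_harmonics(
    w: FlowWaveform, R: float, K: int, fluid: FluidProperties = BLOOD
) -> WomersleyProblem:
    """Turn a measured flow waveform into Womersley pressure-gradient forcing.

    The waveform is Fourier-decomposed into a mean plus K harmonics of the
    cardiac frequency; each flow harmonic is converted to a pressure-gradient
    amplitude through the analytic flow/gradient transfer function, so that
    the analytic (or converged finite-difference) solution of the returned
    problem reproduces the input flow.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    t_closed, q_closed = w.closed_cycle()
    n = max(128, w.times.size)
    if K >= n // 2:
        raise ValueError(f"K={K} exceeds the Nyquist limit of the {n}-point resampling")
    T = w.period
    grid = w.times[0] + T * np.arange(n) / n
    q = np.interp(grid, t_closed, q_closed)
    coeff = np.fft.rfft(q) / n

    omega1 = 2.0 * math.pi / T
    q0 = coeff[0].real
    harmonics: list[tuple[float, complex]] = [
        (0.0, complex(8.0 * fluid.mu * q0 / (math.pi * R**4)))
    ]
    area = math.pi * R**2
    tmp = WomersleyProblem(R, ((0.0, 0.0),), fluid)  # for alpha()
    for k in range(1, K + 1):
        omega = k * omega1
        phi = 2.0 * coeff[k] * np.exp(-1j * omega * w.times[0])  # flow amplitude, t=0 phase
        z = I_3_2 * tmp.alpha(omega)
        f10 = 2.0 * jv(1, z) / (z * jv(0, z))
        A = 1j * fluid.rho * omega * phi / (area * (1.0 - f10))
        harmonics.append((omega, A))
    return WomersleyProblem(R, tuple(harmonics), fluid, period=T)
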