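"""Dimensionless-number and near-wall mesh-sizing chain, plus grid-convergence tools.

For a subject with inlet diameter D, cycle period T and mean/peak flow
rates, the chain is

    Umean = Q / (pi D^2 / 4)
    Re    = 4 Q rho / (pi D mu)
    Wo    = (D/2) sqrt(2 pi f rho / mu),  f = 1/T
    Cf    = Churchill smooth-pipe skin-friction correlation at Re
    tau_w = 1/2 Cf rho Umean^2
    U_T   = sqrt(tau_w / rho)
    dy1   = mu y+ / (rho U_T)

``dy1`` is the first prism-layer cell height satisfying a target y+ (default 1)
for a wall-resolved CFD mesh; the total boundary-layer height follows from a
geometric stack of ``n_layers`` cells.

The grid convergence index (GCI) utilities implement the Richardson-based
discretization-error estimate used for CFD verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .fluids import BLOOD, FluidProperties

__all__ = [
    "BoundaryLayerSpec",
    "FlowCharacterization",
    "GCIResult",
    "reynolds",
    "womersley",
    "skin_friction",
    "first_layer_height",
    "characterize",
    "gci",
    "observed_order",
    "solve_growth_ratio",
]

ML_S_TO_M3_S = 1e-6
MM_TO_M = 1e-3

#: Default prism-layer growth ratio g: solved from a total-to-first-layer
#: height ratio of 7.525 over 5 layers, (g^5-1)/(g-1) = 7.525.
DEFAULT_GROWTH_RATIO = 1.2057


@dataclass(frozen=True)
class BoundaryLayerSpec:
    """Prism boundary-layer sizing: target y+, layer count and stretching."""

    y_plus: float = 1.0
    n_layers: int = 5
    growth_ratio: float = DEFAULT_GROWTH_RATIO
    dy1_mm: float | None = None
    dy_total_mm: float | None = None

    def __post_init__(self) -> None:
        if self.y_plus <= 0 or self.n_layers < 1:
            raise ValueError("y_plus must be positive and n_layers >= 1")
        if self.growth_ratio <= 1:
            raise ValueError(f"growth_ratio must exceed 1, got {self.growth_ratio}")

    @property
    def stack_ratio(self) -> float:
        """dy_total / dy1 for the geometric stack: (g^n - 1)/(g - 1)."""
        g, n = self.growth_ratio, self.n_layers
        return (g**n - 1.0) / (g - 1.0)


@dataclass(frozen=True)
class FlowCharacterization:
    """Derived dimensionless numbers and near-wall scales for one subject."""

    D_mm: float
    T_s: float
    Umean: float  # m/s
    Re_mean: float
    Re_peak: float
    Wo: float
    Cf: float
    tau_w: float  # Pa
    U_T: float  # m/s
    layers: BoundaryLayerSpec


@dataclass(frozen=True)
class GCIResult:
    """Grid convergence index for one refinement pair."""

    Fs: float
    e: float
    r: float
    p: float
    gci: float


def reynolds(Q_ml_s: float, D_mm: float, fluid: FluidProperties = BLOOD) -> float:
    """Pipe Reynolds number Re = 4 Q rho / (pi D mu)."""
    if D_mm <= 0:
        raise ValueError(f"diameter must be positive, got {D_mm}")
    if Q_ml_s < 0:
        raise ValueError(f"flow must be non-negative, got {Q_ml_s}")
    Q = Q_ml_s * ML_S_TO_M3_S
    D = D_mm * MM_TO_M
    return 4.0 * Q * fluid.rho / (math.pi * D * fluid.mu)


def womersley(D_mm: float, T_s: float, fluid: FluidProperties = BLOOD) -> float:
    """Womersley number Wo = (D/2) sqrt(2 pi f rho / mu) with f = 1/T."""
    if D_mm <= 0 or T_s <= 0:
        raise ValueError("diameter and period must be positive")
    f = 1.0 / T_s
    return (D_mm * MM_TO_M / 2.0) * math.sqrt(2.0 * math.pi * f * fluid.rho / fluid.mu)


def skin_friction(Re):
    """Churchill smooth-pipe skin-friction coefficient.

    Cf = 2 [ (8/Re)^12 + ( (2.457 ln((Re/7)^0.9))^16 + (37530/Re)^16 )^-1.5 ]^(1/12)

    Valid across laminar, transitional and turbulent regimes; reduces to
    16/Re in the laminar limit and tracks Blasius at turbulent Re.
    Evaluated in log space so the 12th/16th powers cannot overflow at
    extreme Reynolds numbers.  Accepts scalars or arrays.
    """
    Re = np.asarray(Re, dtype=float)
    if np.any(Re <= 0):
        raise ValueError("Reynolds number must be positive")
    scalar = Re.ndim == 0
    Re = np.atleast_1d(Re)
    log_re = np.log(Re)

    log_lam = 12.0 * (math.log(8.0) - log_re)  # log (8/Re)^12
    # A = (2.457 * 0.9 * ln(Re/7))^16 ; even power, so use |ln(Re/7)|
    inner = 2.457 * 0.9 * (log_re - math.log(7.0))
    with np.errstate(divide="ignore"):
        log_a = 16.0 * np.log(np.abs(inner))
    log_a = np.where(inner == 0.0, -np.inf, log_a)
    log_b = 16.0 * (math.log(37530.0) - log_re)
    log_ab = logsumexp(np.stack([log_a, log_b]), axis=0)
    log_turb = -1.5 * log_ab
    log_bracket = logsumexp(np.stack([log_lam, log_turb]), axis=0)
    cf = 2.0 * np.exp(log_bracket / 12.0)
    return float(cf[0]) if scalar else cf


def first_layer_height(
    Q_ml_s: float,
    D_mm: float,
    fluid: FluidProperties = BLOOD,
    spec: BoundaryLayerSpec | None = None,
) -> BoundaryLayerSpec:
    """Complete a boundary-layer spec with the first-cell height for a target y+.

    Runs the Umean -> Re -> Cf -> tau_w -> U_T chain at the given (mean)
    flow rate and returns the spec with ``dy1_mm`` and ``dy_total_mm``
    filled in.
    """
    if spec is None:
        spec = BoundaryLayerSpec()
    if Q_ml_s <= 0 or D_mm <= 0:
        raise ValueError("flow and diameter must be positive")
    D = D_mm * MM_TO_M
    area = math.pi * D**2 / 4.0
    umean = Q_ml_s * ML_S_TO_M3_S / area
    re = reynolds(Q_ml_s, D_mm, fluid)
    cf = skin_friction(re)
    tau_w = 0.5 * cf * fluid.rho * umean**2
    u_t = math.sqrt(tau_w / fluid.rho)
    dy1 = fluid.mu * spec.y_plus / (fluid.rho * u_t)
    dy1_mm = dy1 / MM_TO_M
    return replace(spec, dy1_mm=dy1_mm, dy_total_mm=dy1_mm * spec.stack_ratio)


def characterize(
    D_mm: float,
    T_s: float,
    Qmean_ml_s: float,
    Qpeak_ml_s: float,
    fluid: FluidProperties = BLOOD,
    spec: BoundaryLayerSpec | None = None,
) -> FlowCharacterization:
    """Full per-subject chain: Re (mean and peak), Wo, Cf, tau_w, U_T, dy1."""
    if Qpeak_ml_s < Qmean_ml_s:
        raise ValueError("peak flow cannot be below mean flow")
    layers = first_layer_height(Qmean_ml_s, D_mm, fluid, spec)
    D = D_mm * MM_TO_M
    umean = Qmean_ml_s * ML_S_TO_M3_S / (math.pi * D**2 / 4.0)
    re_mean = reynolds(Qmean_ml_s, D_mm, fluid)
    cf = skin_friction(re_mean)
    tau_w = 0.5 * cf * fluid.rho * umean**2
    return FlowCharacterization(
        D_mm=D_mm,
        T_s=T_s,
        Umean=umean,
        Re_mean=re_mean,
        Re_peak=reynolds(Qpeak_ml_s, D_mm, fluid),
        Wo=womersley(D_mm, T_s, fluid),
        Cf=float(cf),
        tau_w=tau_w,
        U_T=math.sqrt(tau_w / fluid.rho),
        layers=layers,
    )


def gci(f_fine: float, f_coarse: float, r: float, p: float, Fs: float = 1.25) -> GCIResult:
    """Grid convergence index GCI = Fs * e / (r^p - 1), e = |f_fine - f_coarse| / |f_fine|."""
    if f_fine == 0:
        raise ValueError("fine-grid value must be nonzero")
    if r <= 1:
        raise ValueError(f"refinement ratio must exceed 1, got {r}")
    if p <= 0:
        raise ValueError(f"order of convergence must be positive, got {p}")
    e = abs(f_fine - f_coarse) / abs(f_fine)
    return GCIResult(Fs=Fs, e=e, r=r, p=p, gci=Fs * e / (r**p - 1.0))


def observed_order(f_coarse: float, f_mid: float, f_fine: float, r: float) -> float:
    """Observed order of convergence from three constant-ratio grids.

    p = ln((f_coarse - f_mid) / (f_mid - f_fine)) / ln(r)
    """
    if r <= 1:
        raise ValueError(f"refinement ratio must exceed 1, got {r}")
    num = f_coarse - f_mid
    den = f_mid - f_fine
    if den == 0 or num / den <= 0:
        raise ValueError("grid sequence is not monotonically converging")
    return math.log(num / den) / math.log(r)


def solve_growth_ratio(stack_ratio: float, n_layers: int = 5) -> float:
    """Growth ratio g with (g^n - 1)/(g - 1) equal to a given total/first ratio."""
    if stack_ratio <= n_layers:
        raise ValueError("stack ratio must exceed the layer count for g > 1")
    return brentq(
        lambda g: (g**n_layers - 1.0) / (g - 1.0) - stack_ratio, 1.0 + 1e-9, 10.0
    )
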