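"""Blood rheology constants.

Blood in the proximal aorta is treated as an incompressible Newtonian
fluid; the default density and dynamic viscosity are the values commonly
adopted for large-artery hemodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants.

    Parameters
    ----------
    rho : float
        Density in kg/m^3. Default 1050 (whole blood).
    mu : float
        Dynamic viscosity in Pa*s. Default 3.5e-3 (whole blood).
    """

    rho: float = 1050.0
    mu: float = 3.5e-3

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"density must be positive, got {self.rho}")
        if self.mu <= 0:
            raise ValueError(f"viscosity must be positive, got {self.mu}")

    @property
    def nu(self) -> float:
        """Kinematic viscosity in m^2/s."""
        return self.mu / self.rho


BLOOD = FluidProperties()
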