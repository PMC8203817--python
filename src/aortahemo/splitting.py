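"""Outlet flow splitting by the generalized Murray law.

In the absence of per-outlet flow measurements, the flow fraction sent to
each outlet of an arterial tree is apportioned by a power law of the outlet
diameters, fraction_i = D_i^n / sum_j D_j^n.  The classical Murray cube law
uses n = 3; for large vessels such as the aorta and its arch branches an
exponent of 2 is the better-supported choice and is the default here.  The
descending aorta is treated as an ordinary outlet inside the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .waveform import FlowWaveform

__all__ = ["OutletSet", "FlowSplit", "murray_split", "apply_split"]


@dataclass(frozen=True)
class OutletSet:
    """Named outlets with diameters in mm and the Murray exponent n."""

    outlets: tuple[tuple[str, float], ...]
    exponent: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "outlets", tuple((str(n), float(d)) for n, d in self.outlets))
        if len(self.outlets) < 2:
            raise ValueError("an outlet set needs at least 2 outlets")
        names = [n for n, _ in self.outlets]
        if len(set(names)) != len(names):
            raise ValueError("outlet names must be unique")
        if any(d <= 0 for _, d in self.outlets):
            raise ValueError("all outlet diameters must be positive")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.outlets]

    @property
    def diameters(self) -> np.ndarray:
        return np.array([d for _, d in self.outlets])


@dataclass(frozen=True)
class FlowSplit:
    """Flow fraction per outlet; fractions sum to one."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"fractions must sum to 1, got {total!r}")
        if any(not (0.0 < f < 1.0) for f in self.fractions.values()):
            raise ValueError("each fraction must lie strictly in (0, 1)")

    def as_percentages(self, decimals: int = 0) -> dict[str, float]:
        """Rounded percentage view for table-style reporting."""
        return {k: round(100.0 * v, decimals) for k, v in self.fractions.items()}


def murray_split(s: OutletSet) -> FlowSplit:
    """Split flow among outlets in proportion to diameter^n."""
    dn = s.diameters**s.exponent
    frac = dn / dn.sum()
    return FlowSplit(dict(zip(s.names, frac.tolist())))


def apply_split(split: FlowSplit, inlet: FlowWaveform) -> dict[str, FlowWaveform]:
    """Scale the inlet waveform by each outlet fraction.

    The per-outlet waveforms sum back to the inlet pointwise (conservation).
    """
    return {
        name: FlowWaveform(inlet.times.copy(), frac * inlet.flow, inlet.period)
        for name, frac in split.fractions.items()
    }
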