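"""Matric potential of a porous surface under suction from a hanging liquid column.

The suction applied by a liquid column of height h is rho * g * h; it is
reported as a negative water matric potential in kPa (lower values = drier).
"""

from __future__ import annotations

from dataclasses import dataclass

RHO_WATER_KG_M3 = 998.0  # room temperature
G_M_S2 = 9.81


@dataclass
class HydrationParams:
    h: float  # liquid column height, m (>= 0)
    rho: float = RHO_WATER_KG_M3  # kg/m^3
    g: float = G_M_S2  # m/s^2

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.g <= 0:
            raise ValueError("g must be > 0")
        if self.h < 0:
            raise ValueError("h must be >= 0")


def matric_potential(p: HydrationParams) -> float:
    """Water matric potential in kPa (negative under suction)."""
    return -(p.rho * p.g * p.h) / 1000.0


def column_height_for_potential(
    psi_kpa: float, rho: float = RHO_WATER_KG_M3, g: float = G_M_S2
) -> float:
    """Liquid column height (m) producing the given matric potential (kPa <= 0)."""
    if psi_kpa > 0:
        raise ValueError("psi_kpa must be <= 0 (suction convention)")
    if rho <= 0 or g <= 0:
        raise ValueError("rho and g must be > 0")
    return abs(psi_kpa) * 1000.0 / (rho * g)
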