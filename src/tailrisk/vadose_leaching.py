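"""Vadose-zone leaching/dilution factor LF from subgrade pore water to groundwater.

Two multiplicative steps, following the soil-screening leaching-factor model:

* soil–water partition  Ksw = (θws + Kd·ρb + H·θas) / ρb   [L/kg],
  the volume of pore water (plus sorbed and vapour compartments) holding the
  releasable mass per kg of soil; for non-volatile metals with sorption
  neglected (conservative), Ksw = θws/ρb;
* mixing-zone dilution  LFspw−gw = 1 / (1 + Ugw·δgw / (I·W))   [–],
  the fraction of the groundwater flux under the road that is infiltrate:
  recharge I·W mixes into the lateral groundwater flux Ugw·δgw.

The combined factor LF = LFspw−gw / Ksw (kg/L) converts releasable content
(mg/kg) into a groundwater concentration (mg/L) directly beneath the source.
Dilution never amplifies: LFspw−gw is in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "VadoseParams",
    "soil_water_partition",
    "spw_to_gw_factor",
    "leaching_factor",
]


def soil_water_partition(theta_ws, Kd=0.0, rho_b=1.5, H=0.0, theta_as=0.0):
    """Soil–water partition coefficient Ksw = (θws + Kd·ρb + H·θas)/ρb, L/kg."""
    rho_b = np.asarray(rho_b, dtype=float)
    if np.any(rho_b <= 0):
        raise ValidationError("soil bulk density rho_b must be > 0")
    return (np.asarray(theta_ws, float) + np.asarray(Kd, float) * rho_b
            + np.asarray(H, float) * np.asarray(theta_as, float)) / rho_b


def spw_to_gw_factor(Ugw, delta_gw, I, W):
    """Pore-water→groundwater dilution factor 1/(1 + Ugw·δgw/(I·W)), in (0, 1].

    Ugw and I must share units (m/a here); δgw and W are in m.
    """
    I = np.asarray(I, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(I * W <= 0):
        raise ValidationError("infiltration rate I and road width W must be > 0")
    Ugw = np.asarray(Ugw, dtype=float)
    delta_gw = np.asarray(delta_gw, dtype=float)
    if np.any(Ugw < 0) or np.any(delta_gw < 0):
        raise ValidationError("Ugw and delta_gw must be >= 0")
    return 1.0 / (1.0 + Ugw * delta_gw / (I * W))


def leaching_factor(LFspw_gw, Ksw):
    """Combined leaching factor LF = LFspw−gw / Ksw, kg/L."""
    Ksw = np.asarray(Ksw, dtype=float)
    if np.any(Ksw <= 0):
        raise ValidationError(
            "Ksw must be > 0; degenerate soil parameters "
            "(theta_ws = Kd = H = 0) give no water phase to leach into"
        )
    return np.asarray(LFspw_gw, dtype=float) / Ksw


@dataclass(frozen=True)
class VadoseParams:
    """Resolved vadose-zone parameters for one pipeline evaluation."""

    Ugw: float            # groundwater Darcy velocity, m/a
    delta_gw: float       # groundwater mixing-zone thickness, m
    I: float              # net water infiltration rate into soil, m/a
    W: float              # road width, m
    theta_ws: float = 0.3  # water-filled porosity of unsaturated soil
    theta_as: float = 0.0  # air-filled porosity
    rho_b: float = 1.5     # soil bulk density, kg/L
    Kd: float = 0.0        # solid-water partition coefficient, L/kg
    H: float = 0.0         # dimensionless Henry constant

    def __post_init__(self) -> None:
        for name in ("Ugw", "delta_gw", "I", "W", "theta_ws", "theta_as", "Kd", "H"):
            if getattr(self, name) < 0:
                raise ValidationError(f"vadose parameter {name} must be >= 0")
        if self.rho_b <= 0:
            raise ValidationError("rho_b must be > 0")
        if self.theta_ws + self.theta_as > 1:
            raise ValidationError("theta_ws + theta_as must be <= 1")

    @property
    def Ksw(self) -> float:
        return float(soil_water_partition(self.theta_ws, self.Kd, self.rho_b,
                                          self.H, self.theta_as))

    @property
    def LFspw_gw(self) -> float:
        # zero recharge: nothing infiltrates, the continuous I->0+ limit is 0
        if self.I == 0.0:
            return 0.0
        return float(spw_to_gw_factor(self.Ugw, self.delta_gw, self.I, self.W))

    @property
    def LF(self) -> float:
        """Combined leaching factor, kg/L."""
        return float(leaching_factor(self.LFspw_gw, self.Ksw))
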