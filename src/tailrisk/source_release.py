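"""Exponential source-strength depletion of the subgrade leachate.

The tailings layer holds an available pollutant inventory per unit footprint
area of d·f·ρ·Csw (layer thickness × tailings volume fraction × material
density × availability content).  Infiltrating water at net rate q washes
this inventory out, so the pore-water leachate concentration decays
first-order,

    Ct = C0 · exp(−λ t),      λ = q · Cj / (d · f · ρ · Csw)   [1/a],

which is exactly the rate that exhausts the inventory: the cumulative
leached mass ∫ q·Cj·e^(−λt) dt equals d·f·ρ·Csw.

The availability content Csw (mg/kg) comes from the two-stage availability
leaching test: two batch extractions at liquid-to-solid 50:1 mixed in equal
volumes give a cumulative liquid-to-solid ratio of 100 L/kg, so
Csw = Cj × 100 with Cj the mixed-leachate concentration (mg/L).

The infiltration rate is q = α·P: a dimensionless infiltration coefficient
times annual precipitation, which is what lets regional precipitation drive
the release.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "SourceParams",
    "availability_from_leachate",
    "decay_rate",
    "source_concentration",
    "DEFAULT_LS_RATIO",
]

#: Cumulative liquid-to-solid ratio of the two-stage availability leach
#: (two stages x 50 L/kg), L/kg.
DEFAULT_LS_RATIO = 100.0


def availability_from_leachate(Cj: float, ls_ratio_total: float = DEFAULT_LS_RATIO):
    """Maximum effective release Csw (mg/kg) from the availability-leachate
    concentration Cj (mg/L) at cumulative liquid-to-solid ratio L/S (L/kg)."""
    if ls_ratio_total <= 0:
        raise ValidationError(f"liquid-to-solid ratio must be > 0, got {ls_ratio_total}")
    Cj = np.asarray(Cj, dtype=float)
    if np.any(Cj < 0):
        raise ValidationError("leachate concentration Cj must be >= 0")
    return Cj * ls_ratio_total


def decay_rate(q, Cj, d, f, rho, Csw):
    """Source depletion rate λ = q·Cj/(d·f·ρ·Csw) in 1/a.

    Parameters
    ----------
    q : net infiltration rate through the pavement, m/a (q = α·P).
    Cj : availability-leachate concentration, mg/L.
    d : subgrade layer thickness, m.
    f : tailings volume fraction (0..1).
    rho : subgrade material density, kg/L.
    Csw : availability content, mg/kg.
    """
    q, Cj, d, f, rho, Csw = map(np.asarray, (q, Cj, d, f, rho, Csw))
    denom = d * f * rho * Csw
    if np.any(denom <= 0):
        # Cj = 0 forces Csw = 0: nothing to release, no depletion either.
        if np.ndim(denom) == 0 and Cj == 0:
            return np.zeros_like(np.asarray(q * Cj, dtype=float))
        out = np.where((Csw == 0) & (Cj == 0), 0.0, np.nan)
        if np.isnan(out).any():
            raise ValidationError("decay_rate: d·f·ρ·Csw must be > 0")
        return out
    return q * Cj / denom


def source_concentration(C0, lam, t):
    """Leachate concentration Ct = C0·e^(−λt) at time t (years)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("time must be >= 0")
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValidationError("decay rate must be >= 0")
    return np.asarray(C0, dtype=float) * np.exp(-lam * t)


@dataclass(frozen=True)
class SourceParams:
    """Resolved (scalar) source-term parameters for one pipeline evaluation.

    ``C0`` is the initial subgrade pore-water leachate concentration; by
    default it is f·Cj (the availability leachate diluted by the tailings
    fraction of the layer), selectable via the scenario's
    ``c0_mode`` (``"f_cj"`` or ``"cj"``).
    """

    Cj: float          # availability-leachate concentration, mg/L
    alpha: float       # infiltration coefficient, dimensionless
    precip: float      # annual precipitation, m/a
    d: float           # subgrade layer thickness, m
    f: float           # tailings volume fraction
    rho: float         # subgrade material density, kg/L
    ls_ratio: float = DEFAULT_LS_RATIO  # cumulative L/S of the leach, L/kg
    c0_mode: str = "f_cj"

    def __post_init__(self) -> None:
        for name in ("Cj", "alpha", "precip", "d", "f", "rho", "ls_ratio"):
            if getattr(self, name) < 0:
                raise ValidationError(f"source parameter {name} must be >= 0")
        if self.d <= 0 or self.rho <= 0:
            raise ValidationError("d and rho must be > 0")
        if not 0 <= self.f <= 1:
            raise ValidationError(f"tailings fraction f must be in [0,1], got {self.f}")
        if self.c0_mode not in ("f_cj", "cj"):
            raise ValidationError(f"unknown c0_mode {self.c0_mode!r}")

    @property
    def q(self) -> float:
        """Net infiltration rate q = α·P, m/a."""
        return self.alpha * self.precip

    @property
    def Csw(self) -> float:
        """Availability content, mg/kg."""
        return float(availability_from_leachate(self.Cj, self.ls_ratio))

    @property
    def lam(self) -> float:
        """Depletion rate λ, 1/a (zero for a zero source)."""
        if self.Cj == 0 or self.f == 0:
            return 0.0
        return float(decay_rate(self.q, self.Cj, self.d, self.f, self.rho, self.Csw))

    @property
    def C0(self) -> float:
        """Initial pore-water leachate concentration, mg/L."""
        return self.f * self.Cj if self.c0_mode == "f_cj" else self.Cj

    def concentration(self, t) -> np.ndarray:
        """Pore-water leachate concentration at time t (years), mg/L."""
        return source_concentration(self.C0, self.lam, t)
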