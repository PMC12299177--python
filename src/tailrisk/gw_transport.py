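"""Saturated-zone transport: the dilution–attenuation factor (DAF).

A continuous unit-concentration source at x = 0 feeds a homogeneous 1-D
aquifer with seepage velocity u (m/d) and longitudinal dispersion DL (m²/d).
The classical continuous-injection solution of

    ∂C/∂t = DL ∂²C/∂x² − u ∂C/∂x,      C(0,t) = 1,  C(x,0) = 0,

is

    DAF(x,t) = ½ erfc[(x − u t)/(2√(DL t))]
             + ½ exp(u x / DL) erfc[(x + u t)/(2√(DL t))],

a dimensionless breakthrough fraction in [0, 1], non-decreasing in t and
→ 1 as t → ∞.  The exponentially weighted second term is evaluated through
the scaled complementary error function: with a± = (x ± u t)/(2√(DL t)),
ux/DL − a₊² = −a₋², so the term is ½·exp(−a₋²)·erfcx(a₊) and never
overflows however large u·x/DL gets.

A Crank–Nicolson finite-difference solver for the same transport equation
(optionally with retardation R and first-order decay γ) serves as an
independent numerical oracle for the analytic expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import erfc, erfcx

from .errors import GridError, ValidationError

__all__ = [
    "TransportParams",
    "seepage_velocity",
    "dilution_attenuation_factor",
    "GridSpec",
    "daf_numerical_oracle",
    "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 365.0


def seepage_velocity(K, i, n):
    """Seepage (average linear) velocity u = K·i/n in m/d.

    K hydraulic conductivity (m/d), i hydraulic gradient (dimensionless,
    not per-mille), n effective porosity (fraction, not percent).
    """
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValidationError("effective porosity n must be > 0")
    return np.asarray(K, float) * np.asarray(i, float) / n


def dilution_attenuation_factor(x, u, DL, t):
    """Breakthrough fraction DAF(x, t) ∈ [0, 1]; t in days.

    Broadcasts over array inputs.  ``t <= 0`` returns 0 by convention
    (pre-release).  Overflow-safe for arbitrarily large u·x/DL.
    """
    x, u, DL, t = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (x, u, DL, t))
    )
    if np.any(DL <= 0):
        raise ValidationError("dispersion coefficient DL must be > 0")
    if np.any(u < 0) or np.any(x <= 0):
        raise ValidationError("need u >= 0 and x > 0")
    out = np.zeros(x.shape if x.shape else (1,), dtype=float)
    live = t > 0
    if np.any(live):
        xs, us, ds, ts = (a[live] for a in (x, u, DL, t))
        s = 2.0 * np.sqrt(ds * ts)
        am = (xs - us * ts) / s
        ap = (xs + us * ts) / s
        daf = 0.5 * erfc(am) + 0.5 * np.exp(-(am ** 2)) * erfcx(ap)
        out[live] = np.clip(daf, 0.0, 1.0)
    return out if x.shape else float(out[0])


@dataclass(frozen=True)
class GridSpec:
    """Finite-difference grid for the numerical transport oracle.

    ``length`` defaults to extend well past both the advective front and the
    dispersive spread so the outflow boundary stays inert.
    """

    dx: float          # cell size, m
    dt: float          # time step, d
    length: float = None  # domain length, m (None: auto)

    def resolved_length(self, x: float, u: float, DL: float, t_end: float) -> float:
        if self.length is not None:
            return self.length
        return max(2.0 * x, x + u * t_end + 6.0 * np.sqrt(2.0 * DL * t_end))

    def validate(self, u: float, DL: float) -> None:
        if self.dx <= 0 or self.dt <= 0:
            raise GridError("dx and dt must be > 0")
        peclet = u * self.dx / DL
        if peclet > 2.0:
            raise GridError(
                f"cell Peclet number {peclet:.3g} > 2; refine dx for u={u}, DL={DL}"
            )
        courant = u * self.dt / self.dx
        if courant > 1.0:
            raise GridError(
                f"Courant number {courant:.3g} > 1; refine dt for u={u}, dx={self.dx}"
            )


def daf_numerical_oracle(x, u, DL, t, grid_spec: GridSpec, R=1.0, gamma=0.0):
    """Concentration at (x, t) from a Crank–Nicolson solve of the 1-D
    advection–dispersion equation with unit continuous inlet concentration.

        R ∂C/∂t = DL ∂²C/∂x² − u ∂C/∂x − R γ C

    Central differences in space (requires cell Peclet ≤ 2), trapezoidal in
    time, Dirichlet C = 1 at the inlet and an inert zero-gradient outflow on
    a domain long enough that the front never reaches it.
    """
    if t <= 0:
        return 0.0
    if DL <= 0:
        raise ValidationError("DL must be > 0")
    if R < 1 or gamma < 0:
        raise ValidationError("need R >= 1 and gamma >= 0")
    grid_spec.validate(u, DL)

    L = grid_spec.resolved_length(x, u, DL, t)
    nx = int(np.ceil(L / grid_spec.dx)) + 1
    dx = L / (nx - 1)
    nt = int(np.ceil(t / grid_spec.dt))
    dt = t / nt

    # spatial operator A: (DL C'' - u C')/R - gamma C on interior nodes
    diff = DL / (R * dx ** 2)
    adv = u / (R * 2.0 * dx)
    lower = diff + adv          # coefficient of C[j-1]
    main = -2.0 * diff - gamma  # coefficient of C[j]
    upper = diff - adv          # coefficient of C[j+1]

    # Crank-Nicolson: (I - dt/2 A) C^{n+1} = (I + dt/2 A) C^n, banded form.
    ab = np.zeros((3, nx))
    ab[0, 2:] = -0.5 * dt * upper
    ab[1, 1:-1] = 1.0 - 0.5 * dt * main
    ab[2, :-2] = -0.5 * dt * lower
    # boundary rows: inlet Dirichlet, outlet zero-gradient (C[-1]=C[-2])
    ab[1, 0] = 1.0
    ab[1, -1] = 1.0
    ab[2, -2] = -1.0

    C = np.zeros(nx)
    C[0] = 1.0
    rhs = np.empty(nx)
    for _ in range(nt):
        rhs[1:-1] = (C[1:-1] * (1.0 + 0.5 * dt * main)
                     + C[:-2] * (0.5 * dt * lower)
                     + C[2:] * (0.5 * dt * upper))
        rhs[0] = 1.0
        rhs[-1] = 0.0
        C = solve_banded((1, 1), ab, rhs)
    return float(np.interp(x, np.linspace(0.0, L, nx), C))


@dataclass(frozen=True)
class TransportParams:
    """Resolved saturated-zone parameters for one pipeline evaluation."""

    x: float            # source-to-well distance, m
    K: float            # hydraulic conductivity, m/d
    i: float            # hydraulic gradient, dimensionless
    n: float            # effective porosity, fraction
    DL: float           # longitudinal dispersion coefficient, m2/d
    R: float = 1.0      # retardation factor (conservative default)
    gamma: float = 0.0  # first-order decay, 1/d (conservative default)

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValidationError("x must be > 0")
        if not 0 < self.n < 1:
            raise ValidationError(f"porosity n must be in (0,1), got {self.n}")
        if self.DL <= 0:
            raise ValidationError("DL must be > 0")
        if self.K < 0 or self.i < 0:
            raise ValidationError("K and i must be >= 0")
        if self.R < 1 or self.gamma < 0:
            raise ValidationError("need R >= 1 and gamma >= 0")

    @property
    def u(self) -> float:
        """Seepage velocity, m/d."""
        return float(seepage_velocity(self.K, self.i, self.n))

    def daf(self, t_days):
        """DAF at elapsed time(s) t_days."""
        return dilution_attenuation_factor(self.x, self.u, self.DL, t_days)
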