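"""Dry–wet regional scenarios and the tailings blend-ratio management sweep.

China's dry–wet classification by annual precipitation P:

    arid       P < 200 mm    (modelled U(25, 200))
    semi_arid  200–400 mm
    semi_humid 400–800 mm
    humid      P > 800 mm    (modelled U(800, 1600))

The one-sided outer bounds are closed at 25 mm (hyper-arid floor) and
1600 mm (double the humid threshold, spanning most of monsoonal east
China); both are configurable by overriding ``precip_mm_a`` directly.

In regional mode precipitation drives the model coherently: the net
infiltration q = α·P sets both the source depletion rate λ and the vadose
recharge term I of the mixing-zone dilution (``couple_infiltration``).

The blend sweep fixes the tailings volume fraction f at each grid value
(overriding its base-case distribution), reruns the Monte Carlo with common
random numbers, and records the ratio of the 95th-percentile peak
concentration (the "exposure concentration") to the Class III limit; the
largest f keeping the ratio at or under 1 is the admissible blend limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import DistributionSpec, uniform
from .errors import ValidationError
from .exposure_pipeline import (ExposureSeries, ExposureSummary,
                                default_time_grid, exposure_timeseries,
                                peak_exposure)
from .scenario import ScenarioConfig
from .uncertainty_mc import MCConfig, run_monte_carlo, summarize_mc

__all__ = ["REGIME_BOUNDS_MM", "regime_precipitation", "RegionalResult",
           "run_regional_scenario", "BlendSweepResult",
           "blend_sweep_max_ratio", "DEFAULT_F_GRID"]

#: Annual-precipitation bounds (mm/a) per dry-wet regime, ordered dry -> wet.
REGIME_BOUNDS_MM: dict[str, tuple[float, float]] = {
    "arid": (25.0, 200.0),
    "semi_arid": (200.0, 400.0),
    "semi_humid": (400.0, 800.0),
    "humid": (800.0, 1600.0),
}

DEFAULT_F_GRID = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))


def regime_precipitation(name: str) -> DistributionSpec:
    """Uniform annual-precipitation distribution (mm/a) for a regime."""
    try:
        low, high = REGIME_BOUNDS_MM[name]
    except KeyError:
        raise KeyError(
            f"unknown regime {name!r}; expected one of {sorted(REGIME_BOUNDS_MM)}"
        ) from None
    return uniform(low, high)


def _regional_scenario(scenario: ScenarioConfig, regime: str) -> ScenarioConfig:
    return (scenario
            .with_parameters(precip_mm_a=regime_precipitation(regime))
            .with_options(couple_infiltration=True))


@dataclass(frozen=True)
class RegionalResult:
    """Per-regime central exposure series plus Monte Carlo risk summary."""

    regime: str
    pollutant: str
    central_series: ExposureSeries
    central_summary: ExposureSummary
    mc_summary: dict


def run_regional_scenario(regime: str, pollutant: str,
                          scenario: ScenarioConfig,
                          cfg: MCConfig = MCConfig()) -> RegionalResult:
    """Run one dry–wet regime: a central-parameter time series (precipitation
    at the regime mean, all other parameters at their central values) and a
    full Monte Carlo summary with precipitation drawn from the regime's
    uniform distribution."""
    reg = _regional_scenario(scenario, regime)
    spec = reg.pollutant(pollutant)
    draw = reg.central_draw(pollutant)
    src, vad, tr = reg.resolve(draw)
    t_grid = default_time_grid(reg.horizon_a, reg.dt_a)
    series = exposure_timeseries(src, vad, tr, t_grid, pollutant=pollutant,
                                 source_content_mode=reg.source_content_mode)
    summary = peak_exposure(series, spec)
    mc = summarize_mc(run_monte_carlo(reg, pollutant, cfg), spec)
    return RegionalResult(regime=regime, pollutant=pollutant,
                          central_series=series, central_summary=summary,
                          mc_summary=mc)


@dataclass(frozen=True)
class BlendSweepResult:
    """Exposure-to-standard ratio versus tailings volume fraction."""

    regime: str
    pollutant: str
    f_values: np.ndarray
    ratios: np.ndarray          # p95 peak / Class III limit, per f
    exposure_conc: np.ndarray   # p95 peak, mg/L, per f
    f_max: float                # largest admissible fraction (ratio <= 1)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.ratios) < -1e-12):
            raise ValidationError("blend-sweep ratio decreased along f")


def blend_sweep_max_ratio(regime: str, pollutant: str, f_grid,
                          scenario: ScenarioConfig,
                          cfg: MCConfig = MCConfig()) -> BlendSweepResult:
    """Sweep the tailings volume fraction and find the admissible maximum.

    Each grid value of f overrides the base-case f distribution with a fixed
    value; all sweeps reuse the same seed (common random numbers), so the
    per-draw monotonicity of the peak in f carries over to the p95 ratio.
    ``f_max`` is the largest grid f whose ratio is <= 1; 1.0 means the
    standard is never exceeded, 0.0 that even the smallest grid fraction
    exceeds it.
    """
    f_values = np.asarray(sorted(f_grid), dtype=float)
    if f_values.size == 0:
        raise ValidationError("empty blend-fraction grid")
    if np.any(f_values <= 0) or np.any(f_values > 1):
        raise ValidationError("blend fractions must lie in (0, 1]")
    reg = _regional_scenario(scenario, regime)
    spec = reg.pollutant(pollutant)
    ratios = np.empty_like(f_values)
    conc = np.empty_like(f_values)
    for k, f in enumerate(f_values):
        swept = reg.with_parameters(f=float(f))
        res = run_monte_carlo(swept, pollutant, cfg)
        conc[k] = np.percentile(res.peaks, 95.0)
        ratios[k] = conc[k] / spec.class3_limit
    admissible = f_values[ratios <= 1.0]
    f_max = float(admissible.max()) if admissible.size else 0.0
    return BlendSweepResult(regime=regime, pollutant=pollutant,
                            f_values=f_values, ratios=ratios,
                            exposure_conc=conc, f_max=f_max)
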