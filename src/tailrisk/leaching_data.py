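"""Availability-leaching test results and the Potential Hazard Index screen.

Holds per-sample, per-pollutant leachate concentrations from a two-stage
availability leaching test (NEN 7371 style), computes per-pollutant summary
statistics with a fitted normal distribution, and screens pollutants with the
Potential Hazard Index

    PHI = mean leachate concentration / Class III groundwater limit.

PHI < 1 marks a pollutant that cannot exceed the groundwater standard at a
downgradient well, because every later step (vadose dilution, saturated-zone
dispersion) only reduces concentration.

Below-detection entries are stored as the detection limit with a flag; for
statistics they are substituted at half the detection limit, the standard
conservative convention for lightly censored environmental data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .distributions import DistributionSpec, normal
from .errors import FormatError, ValidationError

__all__ = [
    "LeachingDataset",
    "LeachingStats",
    "PollutantSpec",
    "load_leaching_table",
    "summarize_pollutant",
    "compute_phi",
]

REQUIRED_COLUMNS = ("sample_id", "pollutant", "concentration_mg_L")


@dataclass(frozen=True)
class LeachingStats:
    """Per-pollutant summary of leachate concentrations (mg/L)."""

    pollutant: str
    mean: float
    sd: float
    minimum: float
    maximum: float
    n: int
    fitted: DistributionSpec = None  # normal fit used for Monte Carlo draws

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"{self.pollutant}: need >= 2 samples, got {self.n}")
        tol = 1e-9 * max(abs(self.minimum), abs(self.maximum), 1e-300)
        if not (self.minimum - tol <= self.mean <= self.maximum + tol):
            raise ValidationError(f"{self.pollutant}: min <= mean <= max violated")
        if self.sd < 0:
            raise ValidationError(f"{self.pollutant}: sd < 0")


@dataclass(frozen=True)
class PollutantSpec:
    """Pollutant identity, its Class III groundwater limit and the leachate
    concentration distribution Cj used as the uncertain source term."""

    name: str
    class3_limit: float  # mg/L
    leachate_dist: DistributionSpec

    def __post_init__(self) -> None:
        if self.class3_limit <= 0:
            raise ValidationError(
                f"{self.name}: Class III limit must be > 0, got {self.class3_limit}"
            )


class LeachingDataset:
    """Per-sample, per-pollutant availability-leachate concentrations.

    Thin wrapper over a tidy :class:`pandas.DataFrame` with columns
    ``sample_id, pollutant, concentration_mg_L, below_detection``.
    """

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r}")
        if "below_detection" not in df.columns:
            df["below_detection"] = False
        df["below_detection"] = df["below_detection"].astype(bool)
        df["concentration_mg_L"] = pd.to_numeric(df["concentration_mg_L"])
        if (df["concentration_mg_L"] < 0).any():
            bad = df.loc[df["concentration_mg_L"] < 0].iloc[0]
            raise ValidationError(
                f"negative concentration for {bad['pollutant']} in sample "
                f"{bad['sample_id']}"
            )
        dup = df.duplicated(subset=["sample_id", "pollutant"])
        if dup.any():
            raise ValidationError(
                f"duplicate (sample_id, pollutant) pairs: "
                f"{df.loc[dup, ['sample_id', 'pollutant']].to_records(index=False)[:3]}"
            )
        self.frame = df.reset_index(drop=True)

    @property
    def pollutants(self) -> list[str]:
        return sorted(self.frame["pollutant"].unique())

    def n_samples(self, pollutant: str) -> int:
        return int((self.frame["pollutant"] == pollutant).sum())

    def concentrations(self, pollutant: str) -> np.ndarray:
        """Concentrations for one pollutant with censored entries substituted
        at half the detection limit (the stored value is the detection limit)."""
        sub = self.frame[self.frame["pollutant"] == pollutant]
        if sub.empty:
            raise KeyError(f"pollutant {pollutant!r} not in dataset")
        c = sub["concentration_mg_L"].to_numpy(float).copy()
        cens = sub["below_detection"].to_numpy(bool)
        c[cens] = 0.5 * c[cens]
        return c

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def load_leaching_table(path) -> LeachingDataset:
    """Read a delimited leaching table (CSV) into a validated dataset.

    Below-detection rows carry the detection limit in the concentration
    column with ``below_detection`` true.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse leaching table {path}: {exc}") from exc
    return LeachingDataset(df)


def summarize_pollutant(data: LeachingDataset, pollutant: str) -> LeachingStats:
    """Summary statistics and a fitted normal distribution for one pollutant.

    Normality is assumed for the downstream Monte Carlo source term; a
    Shapiro–Wilk check is run and reported as a warning only.
    """
    c = data.concentrations(pollutant)
    n = len(c)
    if n < 2:
        raise ValidationError(f"{pollutant}: need >= 2 samples, got {n}")
    mean = float(np.mean(c))
    sd = float(np.std(c, ddof=1))
    if 3 <= n <= 5000:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = sps.shapiro(c).pvalue
        if p < 0.05:
            warnings.warn(
                f"{pollutant}: Shapiro-Wilk p={p:.3g} < 0.05; normal fit is "
                "assumed anyway",
                stacklevel=2,
            )
    return LeachingStats(
        pollutant=pollutant,
        mean=mean,
        sd=sd,
        minimum=float(np.min(c)),
        maximum=float(np.max(c)),
        n=n,
        fitted=normal(mean, sd),
    )


def compute_phi(stats: LeachingStats, spec: PollutantSpec) -> float:
    """Potential Hazard Index: mean leachate concentration / Class III limit."""
    if spec.class3_limit <= 0:
        raise ValidationError(f"{spec.name}: limit must be > 0")
    return stats.mean / spec.class3_limit
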