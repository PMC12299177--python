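"""Parameter distributions for uncertainty propagation.

Every uncertain scenario quantity is described by a :class:`DistributionSpec`:
a normal (optionally truncated below), a uniform, or a degenerate fixed value.
Physical quantities here are non-negative, so normals truncate at zero by
default.  Sampling is inverse-transform: each draw consumes exactly one
uniform variate from the caller's generator, so draw streams are stable when
the number of iterations changes (the first ``n`` draws of a longer run equal
the draws of a shorter run with the same seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy import stats

from .errors import SchemaError, ValidationError

__all__ = ["DistributionSpec", "normal", "uniform", "fixed"]

_KINDS = ("normal", "uniform", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """A scalar parameter distribution: normal, uniform or fixed.

    Parameters
    ----------
    kind
        One of ``"normal"``, ``"uniform"``, ``"fixed"``.
    params
        ``(mean, sd)`` for normal, ``(low, high)`` for uniform,
        ``(value,)`` for fixed.
    lower
        Truncation bound for normals (default 0; use ``-inf`` to disable).
    """

    kind: str
    params: tuple[float, ...]
    lower: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SchemaError(f"unknown distribution kind {self.kind!r}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if self.kind == "normal":
            if len(p) != 2:
                raise SchemaError("normal distribution needs (mean, sd)")
            if p[1] < 0:
                raise ValidationError(f"sd must be >= 0, got {p[1]}")
        elif self.kind == "uniform":
            if len(p) != 2:
                raise SchemaError("uniform distribution needs (low, high)")
            if p[0] > p[1]:
                raise ValidationError(f"uniform low {p[0]} > high {p[1]}")
        else:
            if len(p) != 1:
                raise SchemaError("fixed distribution needs a single value")

    # -- central (deterministic) value -----------------------------------
    def central(self) -> float:
        """Scalar used for central-value runs: normal mean, uniform
        midpoint, or the fixed value."""
        if self.kind == "normal":
            return self.params[0]
        if self.kind == "uniform":
            return 0.5 * (self.params[0] + self.params[1])
        return self.params[0]

    # -- sampling --------------------------------------------------------
    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` values, truncating normals at ``lower``."""
        if self.kind == "fixed":
            return np.full(size, self.params[0])
        u = rng.random(size)
        if self.kind == "uniform":
            low, high = self.params
            return low + u * (high - low)
        mean, sd = self.params
        if sd == 0.0:
            return np.full(size, mean)
        if math.isinf(self.lower):
            return stats.norm.ppf(u, loc=mean, scale=sd)
        a = (self.lower - mean) / sd
        return stats.truncnorm.ppf(u, a=a, b=np.inf, loc=mean, scale=sd)

    # -- (de)serialization ------------------------------------------------
    @classmethod
    def from_obj(cls, obj: Any, *, lower: float = 0.0) -> "DistributionSpec":
        """Build from a YAML-ish object: a bare number means ``fixed``;
        a mapping uses ``{dist: normal, mean: .., sd: ..}`` /
        ``{dist: uniform, low: .., high: ..}`` / ``{dist: fixed, value: ..}``."""
        if isinstance(obj, DistributionSpec):
            return obj
        if isinstance(obj, (int, float)):
            return cls("fixed", (float(obj),), lower=lower)
        if isinstance(obj, Mapping):
            d = dict(obj)
            kind = d.pop("dist", None)
            lo = float(d.pop("truncate_at", lower))
            if kind == "normal":
                spec = cls("normal", (d.pop("mean"), d.pop("sd")), lower=lo)
            elif kind == "uniform":
                spec = cls("uniform", (d.pop("low"), d.pop("high")), lower=lo)
            elif kind == "fixed":
                spec = cls("fixed", (d.pop("value"),), lower=lo)
            else:
                raise SchemaError(f"unknown distribution kind {kind!r}")
            if d:
                raise SchemaError(f"unexpected distribution keys {sorted(d)}")
            return spec
        raise SchemaError(f"cannot interpret {obj!r} as a distribution")

    def to_obj(self) -> Any:
        if self.kind == "fixed":
            return self.params[0]
        if self.kind == "normal":
            return {"dist": "normal", "mean": self.params[0], "sd": self.params[1]}
        return {"dist": "uniform", "low": self.params[0], "high": self.params[1]}


def normal(mean: float, sd: float, lower: float = 0.0) -> DistributionSpec:
    return DistributionSpec("normal", (mean, sd), lower=lower)


def uniform(low: float, high: float) -> DistributionSpec:
    return DistributionSpec("uniform", (low, high))


def fixed(value: float) -> DistributionSpec:
    return DistributionSpec("fixed", (value,))
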