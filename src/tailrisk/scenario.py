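"""Scenario configuration: the full parameter inventory of a risk run.

A scenario bundles the pollutant list (identity, Class III groundwater
limit, leachate-concentration distribution), every hydrogeological / road
parameter as a :class:`~tailrisk.distributions.DistributionSpec` (fixed
values are degenerate distributions), and run options.  Units are encoded
in the parameter names (``_m``, ``_m_a``, ``_mm_a``, ``_kg_L``, ``_m_d``,
``_m2_d``, ``_per_mille``, ``_pct``); unit conversions to the internal
m/a–m/d–mg/L system happen in :meth:`ScenarioConfig.resolve`.

The default inventory is the base case of the underlying study site: a
humid area with 900 mm/a precipitation, a 100 m source-to-well distance,
and six heavy metals (As, Mn, Ba, Ni, Co, Pb) with normal leachate
distributions fitted to availability-leaching tests.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, replace
from typing import Mapping

import yaml

from .distributions import DistributionSpec, fixed, normal, uniform
from .errors import SchemaError, ValidationError
from .exposure_pipeline import DEFAULT_DT_A, DEFAULT_HORIZON_A
from .gw_transport import TransportParams
from .leaching_data import PollutantSpec
from .source_release import DEFAULT_LS_RATIO, SourceParams
from .vadose_leaching import VadoseParams

__all__ = ["ScenarioConfig", "load_scenario", "SYMBOLS", "DEFAULT_POLLUTANTS",
           "default_scenario"]

SCHEMA_VERSION = 1

#: Uncertain / fixed scenario symbols in canonical sampling order.  The
#: pollutant leachate concentration ``Cj`` is sampled first; the order is
#: frozen so seeds are portable across runs and releases.
SYMBOLS = (
    "Cj",
    "alpha",
    "precip_mm_a",
    "d_m",
    "f",
    "rho_kg_L",
    "Ugw_m_a",
    "delta_gw_m",
    "I_m_a",
    "W_m",
    "theta_ws",
    "theta_as",
    "rho_b_kg_L",
    "Kd_L_kg",
    "H",
    "x_m",
    "K_m_d",
    "i_per_mille",
    "n_pct",
    "DL_m2_d",
)

#: Base-case parameter inventory (study-site defaults).
DEFAULT_PARAMETERS: dict[str, DistributionSpec] = {
    "alpha": normal(0.2, 0.05),
    "precip_mm_a": fixed(900.0),
    "d_m": uniform(0.3, 1.2),
    "f": uniform(0.1, 0.5),
    "rho_kg_L": normal(2.0, 0.2),
    "Ugw_m_a": fixed(25.0),
    "delta_gw_m": normal(2.0, 0.082),
    "I_m_a": fixed(0.3),
    "W_m": uniform(3.5, 30.0),
    "theta_ws": fixed(0.3),
    "theta_as": fixed(0.0),
    "rho_b_kg_L": fixed(1.5),
    "Kd_L_kg": fixed(0.0),
    "H": fixed(0.0),
    "x_m": fixed(100.0),
    "K_m_d": uniform(10.0, 50.0),
    "i_per_mille": uniform(3.0, 6.0),
    "n_pct": uniform(30.0, 50.0),
    "DL_m2_d": uniform(5.0, 10.0),
}

#: Default pollutant inventory: Class III limit (mg/L) and fitted normal
#: leachate distribution (mean, sd in mg/L).
DEFAULT_POLLUTANTS: dict[str, PollutantSpec] = {
    "As": PollutantSpec("As", 0.01, normal(0.040, 0.005)),
    "Mn": PollutantSpec("Mn", 0.1, normal(1.860, 0.600)),
    "Ba": PollutantSpec("Ba", 0.7, normal(2.600, 0.300)),
    "Ni": PollutantSpec("Ni", 0.02, normal(0.080, 0.010)),
    "Co": PollutantSpec("Co", 0.05, normal(0.080, 0.006)),
    "Pb": PollutantSpec("Pb", 0.01, normal(0.050, 0.010)),
}

# parameters that must resolve to a strictly positive central value
_STRICTLY_POSITIVE = ("d_m", "rho_kg_L", "W_m", "rho_b_kg_L", "x_m",
                      "K_m_d", "i_per_mille", "n_pct", "DL_m2_d", "I_m_a")


@dataclass(frozen=True)
class ScenarioConfig:
    """Validated scenario: pollutants, parameter distributions, run options."""

    pollutants: dict[str, PollutantSpec]
    parameters: dict[str, DistributionSpec]
    ls_ratio_L_kg: float = DEFAULT_LS_RATIO
    c0_mode: str = "f_cj"                    # "f_cj" | "cj"
    source_content_mode: str = "leachate"    # "leachate" | "availability"
    couple_infiltration: bool = False        # vadose I := alpha * precip
    horizon_a: float = DEFAULT_HORIZON_A
    dt_a: float = DEFAULT_DT_A

    def __post_init__(self) -> None:
        missing = [s for s in SYMBOLS[1:] if s not in self.parameters]
        if missing:
            raise SchemaError(f"scenario is missing parameters {missing}")
        unknown = sorted(set(self.parameters) - set(SYMBOLS[1:]))
        if unknown:
            raise SchemaError(f"unknown scenario parameters {unknown}")
        for sym, dist in self.parameters.items():
            c = dist.central()
            if c < 0:
                raise ValidationError(f"parameter {sym} has negative central value {c}")
            if sym in _STRICTLY_POSITIVE and c <= 0:
                raise ValidationError(f"parameter {sym} must be > 0, got {c}")
        if self.c0_mode not in ("f_cj", "cj"):
            raise SchemaError(f"unknown c0_mode {self.c0_mode!r}")
        if self.source_content_mode not in ("leachate", "availability"):
            raise SchemaError(
                f"unknown source_content_mode {self.source_content_mode!r}")
        if self.horizon_a <= 0 or self.dt_a <= 0 or self.dt_a > self.horizon_a:
            raise ValidationError("need 0 < dt_a <= horizon_a")
        if not self.pollutants:
            raise SchemaError("scenario must name at least one pollutant")

    # -- access -----------------------------------------------------------
    def pollutant(self, name: str) -> PollutantSpec:
        try:
            return self.pollutants[name]
        except KeyError:
            raise KeyError(
                f"pollutant {name!r} not in scenario "
                f"(have {sorted(self.pollutants)})") from None

    def dist(self, symbol: str, pollutant: str) -> DistributionSpec:
        """Distribution for one canonical symbol."""
        if symbol == "Cj":
            return self.pollutant(pollutant).leachate_dist
        try:
            return self.parameters[symbol]
        except KeyError:
            raise KeyError(f"unknown scenario symbol {symbol!r}") from None

    # -- resolution into physical parameter objects -----------------------
    def resolve(self, draw: Mapping[str, float]
                ) -> tuple[SourceParams, VadoseParams, TransportParams]:
        """Turn one draw (canonical symbols -> values) into validated
        source/vadose/transport parameter sets, applying unit conversions
        and the precipitation–infiltration coupling."""
        g = draw.__getitem__
        precip_m_a = g("precip_mm_a") / 1000.0
        src = SourceParams(
            Cj=g("Cj"), alpha=g("alpha"), precip=precip_m_a,
            d=g("d_m"), f=g("f"), rho=g("rho_kg_L"),
            ls_ratio=self.ls_ratio_L_kg, c0_mode=self.c0_mode,
        )
        I_eff = src.q if self.couple_infiltration else g("I_m_a")
        vad = VadoseParams(
            Ugw=g("Ugw_m_a"), delta_gw=g("delta_gw_m"), I=I_eff, W=g("W_m"),
            theta_ws=g("theta_ws"), theta_as=g("theta_as"),
            rho_b=g("rho_b_kg_L"), Kd=g("Kd_L_kg"), H=g("H"),
        )
        tr = TransportParams(
            x=g("x_m"), K=g("K_m_d"), i=g("i_per_mille") / 1000.0,
            n=g("n_pct") / 100.0, DL=g("DL_m2_d"),
        )
        return src, vad, tr

    def central_draw(self, pollutant: str) -> dict[str, float]:
        """Central value of every symbol (normal mean, uniform midpoint)."""
        return {s: self.dist(s, pollutant).central() for s in SYMBOLS}

    # -- derived scenarios -------------------------------------------------
    def with_parameters(self, **updates) -> "ScenarioConfig":
        """Copy with some parameter distributions replaced (values are
        coerced through :meth:`DistributionSpec.from_obj`)."""
        params = dict(self.parameters)
        for sym, obj in updates.items():
            if sym not in params:
                raise KeyError(f"unknown scenario symbol {sym!r}")
            params[sym] = DistributionSpec.from_obj(obj)
        return replace(self, parameters=params)

    def with_options(self, **updates) -> "ScenarioConfig":
        return replace(self, **updates)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "pollutants": [
                {"name": p.name, "class3_limit_mg_L": p.class3_limit,
                 "leachate_mg_L": p.leachate_dist.to_obj()}
                for p in self.pollutants.values()
            ],
            "parameters": {s: d.to_obj() for s, d in self.parameters.items()},
            "options": {
                "ls_ratio_L_kg": self.ls_ratio_L_kg,
                "c0_mode": self.c0_mode,
                "source_content_mode": self.source_content_mode,
                "couple_infiltration": self.couple_infiltration,
                "horizon_a": self.horizon_a,
                "dt_a": self.dt_a,
            },
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable sha256 of the canonical YAML form (provenance stamp)."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()


def _parse_pollutants(items) -> dict[str, PollutantSpec]:
    out: dict[str, PollutantSpec] = {}
    for item in items:
        if isinstance(item, str):  # name only: fill from defaults
            if item not in DEFAULT_POLLUTANTS:
                raise SchemaError(f"unknown default pollutant {item!r}")
            out[item] = DEFAULT_POLLUTANTS[item]
            continue
        d = dict(item)
        name = d.pop("name")
        limit = d.pop("class3_limit_mg_L",
                      DEFAULT_POLLUTANTS[name].class3_limit
                      if name in DEFAULT_POLLUTANTS else None)
        leach = d.pop("leachate_mg_L",
                      DEFAULT_POLLUTANTS[name].leachate_dist
                      if name in DEFAULT_POLLUTANTS else None)
        if d:
            raise SchemaError(f"unknown pollutant keys {sorted(d)} for {name!r}")
        if limit is None or leach is None:
            raise SchemaError(
                f"pollutant {name!r} needs class3_limit_mg_L and leachate_mg_L")
        out[name] = PollutantSpec(name, float(limit),
                                  DistributionSpec.from_obj(leach))
    return out


def default_scenario(pollutants=("As", "Mn", "Ba", "Ni", "Co", "Pb")
                     ) -> ScenarioConfig:
    """The base-case scenario with the default parameter inventory."""
    return ScenarioConfig(
        pollutants={n: DEFAULT_POLLUTANTS[n] for n in pollutants},
        parameters=dict(DEFAULT_PARAMETERS),
    )


def load_scenario(path) -> ScenarioConfig:
    """Load and validate a YAML scenario; unnamed parameters get the
    default (base-case) inventory values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise SchemaError(f"scenario file {path} is not a mapping")
    raw = copy.deepcopy(dict(raw))
    version = raw.pop("schema", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {version!r}")
    pollutants = _parse_pollutants(raw.pop("pollutants", []))
    if not pollutants:
        raise SchemaError("scenario must list at least one pollutant")
    params = dict(DEFAULT_PARAMETERS)
    for sym, obj in dict(raw.pop("parameters", {})).items():
        if sym not in params:
            raise SchemaError(f"unknown parameter key {sym!r}")
        params[sym] = DistributionSpec.from_obj(obj)
    options = dict(raw.pop("options", {}))
    mc = raw.pop("mc", None)  # tolerated here; consumed by the CLI layer
    if raw:
        raise SchemaError(f"unknown top-level scenario keys {sorted(raw)}")
    known_options = {"ls_ratio_L_kg", "c0_mode", "source_content_mode",
                     "couple_infiltration", "horizon_a", "dt_a"}
    unknown = set(options) - known_options
    if unknown:
        raise SchemaError(f"unknown option keys {sorted(unknown)}")
    cfg = ScenarioConfig(pollutants=pollutants, parameters=params, **options)
    # attach mc block for the CLI without making it part of the frozen schema
    object.__setattr__(cfg, "_mc_block", mc)
    return cfg
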