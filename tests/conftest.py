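import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tailrisk as tr

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEED = 1234


@pytest.fixture(scope="session")
def scenario():
    """Base-case scenario: humid study site at 900 mm/a, default inventory."""
    return tr.default_scenario()


@pytest.fixture(scope="session")
def ni_spec(scenario):
    return scenario.pollutant("Ni")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Synthetic study fixture (leaching CSV + scenario YAML)."""
    out = tmp_path_factory.mktemp("fixture")
    tr.generate_study_fixture(out, seed=SEED)
    return out


@pytest.fixture(scope="session")
def all_fixed_scenario(scenario):
    """Scenario with every distribution collapsed to its central value."""
    sc = scenario.with_parameters(
        **{s: scenario.parameters[s].central() for s in scenario.parameters})
    fixed_pollutants = {
        n: tr.PollutantSpec(n, p.class3_limit, tr.fixed(p.leachate_dist.central()))
        for n, p in scenario.pollutants.items()
    }
    return sc.with_options(pollutants=fixed_pollutants)
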