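import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import erfc

from tailrisk.errors import GridError, ValidationError
from tailrisk.gw_transport import (GridSpec, TransportParams,
                                   daf_numerical_oracle,
                                   dilution_attenuation_factor,
                                   seepage_velocity)


@pytest.mark.parametrize(
    "K, i, n, expected",
    [(30.0, 0.0045, 0.4, 0.3375), (10.0, 0.003, 0.5, 0.06), (30.0, 0.0, 0.4, 0.0)],
)
def test_seepage_velocity(K, i, n, expected):
    assert seepage_velocity(K, i, n) == pytest.approx(expected)


def test_seepage_velocity_requires_positive_porosity():
    with pytest.raises(ValidationError):
        seepage_velocity(30.0, 0.0045, 0.0)


def test_daf_reference_value():
    # 0.5*erfc(0) + 0.5*e^2*erfc(sqrt(2)) evaluated independently
    expected = 0.5 + 0.5 * np.exp(2.0) * erfc(200.0 / (2 * np.sqrt(5000.0)))
    got = dilution_attenuation_factor(100.0, 0.1, 5.0, 1000.0)
    assert got == pytest.approx(expected, rel=1e-10)
    assert got == pytest.approx(0.668, abs=5e-4)


def test_daf_limits():
    assert dilution_attenuation_factor(100, 0.1, 5, 1e10) == pytest.approx(1.0)
    assert dilution_attenuation_factor(100, 0.1, 5, 1e-6) == pytest.approx(0.0, abs=1e-12)
    assert dilution_attenuation_factor(100, 0.1, 5, 0.0) == 0.0
    assert dilution_attenuation_factor(100, 0.1, 5, -5.0) == 0.0


def test_daf_breakthrough_midpoint():
    """At t = x/u the leading erfc term alone contributes 0.5."""
    x, u, DL = 100.0, 0.25, 5.0
    daf = dilution_attenuation_factor(x, u, DL, x / u)
    assert daf >= 0.5


def test_daf_no_overflow_extreme_peclet():
    # u*x/DL up to 2e4: naive exp(ux/DL) overflows, scaled form must not
    for uxdl in (50.0, 700.0, 2e4):
        u = 1.0
        DL = u * 100.0 / uxdl
        v = dilution_attenuation_factor(100.0, u, DL, 90.0)
        assert np.isfinite(v) and 0.0 <= v <= 1.0


def test_daf_rejects_bad_inputs():
    with pytest.raises(ValidationError):
        dilution_attenuation_factor(100, 0.1, 0.0, 10.0)
    with pytest.raises(ValidationError):
        dilution_attenuation_factor(100, -0.1, 5.0, 10.0)


@given(st.floats(0.01, 1.0), st.floats(5.0, 10.0))
def test_daf_monotone_in_time(u, DL):
    t = np.linspace(1.0, 5000.0, 300)
    daf = dilution_attenuation_factor(100.0, u, DL, t)
    assert np.all(np.diff(daf) >= -1e-12)
    assert np.all((daf >= 0) & (daf <= 1))


def test_oracle_pure_diffusion_closed_form():
    """With u=0 the transport equation reduces to diffusion with
    C(x,t) = erfc(x / (2 sqrt(DL t)))."""
    x, DL, t = 100.0, 5.0, 1000.0
    num = daf_numerical_oracle(x, 0.0, DL, t, GridSpec(dx=1.0, dt=2.0))
    assert num == pytest.approx(erfc(x / (2 * np.sqrt(DL * t))), abs=1e-3)


def test_oracle_matches_analytic_solution():
    num = daf_numerical_oracle(100.0, 0.1, 5.0, 1000.0, GridSpec(dx=1.0, dt=2.0))
    ana = dilution_attenuation_factor(100.0, 0.1, 5.0, 1000.0)
    assert num == pytest.approx(ana, abs=5e-3)


def test_oracle_grid_convergence():
    """Refining the grid 2x shrinks the error against the analytic solution."""
    ana = dilution_attenuation_factor(100.0, 0.2, 5.0, 700.0)
    err = [abs(daf_numerical_oracle(100.0, 0.2, 5.0, 700.0,
                                    GridSpec(dx=dx, dt=dt)) - ana)
           for dx, dt in [(4.0, 8.0), (2.0, 4.0), (1.0, 2.0)]]
    assert err[1] < err[0] and err[2] < err[1]


def test_oracle_rejects_unstable_grids():
    with pytest.raises(GridError):  # cell Peclet > 2
        daf_numerical_oracle(100.0, 1.0, 5.0, 100.0, GridSpec(dx=20.0, dt=1.0))
    with pytest.raises(GridError):  # Courant > 1
        daf_numerical_oracle(100.0, 1.0, 5.0, 100.0, GridSpec(dx=1.0, dt=5.0))


def test_transport_params_derived_velocity_and_validation():
    p = TransportParams(x=100.0, K=30.0, i=0.0045, n=0.4, DL=7.5)
    assert p.u == pytest.approx(0.3375)
    assert p.daf(1e9) == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        TransportParams(x=100.0, K=30.0, i=0.0045, n=1.2, DL=7.5)
    with pytest.raises(ValidationError):
        TransportParams(x=0.0, K=30.0, i=0.0045, n=0.4, DL=7.5)
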