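import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tailrisk as tr
from tailrisk.errors import FormatError, ValidationError
from tailrisk.leaching_data import (LeachingDataset, compute_phi,
                                    load_leaching_table, summarize_pollutant)


def _table(rows):
    return LeachingDataset(pd.DataFrame(rows))


def test_load_three_row_table(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text(
        "sample_id,pollutant,concentration_mg_L,below_detection\n"
        "S1,Ni,0.08,False\nS2,Ni,0.09,False\nS3,Ni,0.07,False\n"
    )
    data = load_leaching_table(p)
    assert data.n_samples("Ni") == 3
    assert data.pollutants == ["Ni"]


def test_negative_concentration_rejected(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("sample_id,pollutant,concentration_mg_L\nS1,Ni,-0.01\n")
    with pytest.raises(ValidationError):
        load_leaching_table(p)


def test_missing_column_rejected(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("sample,metal,conc\nS1,Ni,0.01\n")
    with pytest.raises(FormatError):
        load_leaching_table(p)


def test_duplicate_sample_pollutant_rejected():
    with pytest.raises(ValidationError):
        _table([
            {"sample_id": "S1", "pollutant": "Ni", "concentration_mg_L": 0.1},
            {"sample_id": "S1", "pollutant": "Ni", "concentration_mg_L": 0.2},
        ])


def test_synthetic_round_trip(fixture_dir):
    """Writing the synthetic table and reading it back is lossless."""
    spec = tr.synthetic_data.default_synthetic_spec(seed=1234)
    data = tr.generate_leaching_dataset(spec)
    loaded = load_leaching_table(fixture_dir / "leaching.csv")
    pd.testing.assert_frame_equal(data.frame, loaded.frame)


def test_summarize_hand_example():
    data = _table([
        {"sample_id": f"S{k}", "pollutant": "X", "concentration_mg_L": c}
        for k, c in enumerate([0.06, 0.08, 0.10])
    ])
    s = summarize_pollutant(data, "X")
    assert s.mean == pytest.approx(0.08)
    assert s.minimum == pytest.approx(0.06)
    assert s.maximum == pytest.approx(0.10)
    assert s.n == 3
    assert s.fitted.kind == "normal"
    assert s.fitted.central() == pytest.approx(0.08)


def test_summarize_unknown_pollutant():
    data = _table([{"sample_id": "S1", "pollutant": "X",
                    "concentration_mg_L": 1.0},
                   {"sample_id": "S2", "pollutant": "X",
                    "concentration_mg_L": 2.0}])
    with pytest.raises(KeyError):
        summarize_pollutant(data, "Y")


def test_censored_values_use_half_detection_limit():
    data = _table([
        {"sample_id": "S1", "pollutant": "X", "concentration_mg_L": 0.10,
         "below_detection": False},
        {"sample_id": "S2", "pollutant": "X", "concentration_mg_L": 0.02,
         "below_detection": True},  # detection limit stored
    ])
    c = data.concentrations("X")
    assert sorted(c) == pytest.approx([0.01, 0.10])


def test_parameter_recovery_from_generating_normal():
    """Mean of a synthetic Ni dataset drawn from N(0.080, 0.010), n=100,
    stays within 3 standard errors of the generating mean."""
    spec = tr.SyntheticSpec(
        pollutants=(tr.synthetic_data.PollutantGen("Ni", 0.080, 0.010),),
        n_samples=100, seed=1234)
    s = summarize_pollutant(tr.generate_leaching_dataset(spec), "Ni")
    assert abs(s.mean - 0.080) < 3 * 0.010 / np.sqrt(100)


def test_large_sample_recovers_printed_statistics():
    """Re-summarizing a large synthetic Mn sample recovers the generating
    mean 1.860 and sd 0.600 within Monte Carlo error."""
    spec = tr.SyntheticSpec(
        pollutants=(tr.synthetic_data.PollutantGen("Mn", 1.860, 0.600),),
        n_samples=20_000, seed=1234)
    s = summarize_pollutant(tr.generate_leaching_dataset(spec), "Mn")
    assert s.mean == pytest.approx(1.860, abs=4 * 0.600 / np.sqrt(20_000))
    assert s.sd == pytest.approx(0.600, rel=0.03)


@pytest.mark.parametrize(
    "mean, limit, expected",
    [
        (0.1, 0.1, 1.0),        # mean equal to the standard
        (1.860, 0.1, 18.6),     # manganese
        (2.600, 0.7, 3.714286), # barium
    ],
)
def test_phi_is_mean_over_limit(mean, limit, expected):
    stats = tr.LeachingStats("X", mean, 0.0, mean, mean, 2)
    spec = tr.PollutantSpec("X", limit, tr.fixed(mean))
    assert compute_phi(stats, spec) == pytest.approx(expected, rel=1e-6)


def test_phi_zero_limit_rejected():
    with pytest.raises(ValidationError):
        tr.PollutantSpec("X", 0.0, tr.fixed(1.0))


@given(st.floats(1e-3, 1e3))
def test_phi_scale_invariance(c):
    """Scaling mean and limit together leaves PHI unchanged."""
    base = compute_phi(tr.LeachingStats("X", 1.86, 0.0, 1.86, 1.86, 2),
                       tr.PollutantSpec("X", 0.1, tr.fixed(1.86)))
    scaled = compute_phi(
        tr.LeachingStats("X", 1.86 * c, 0.0, 1.86 * c, 1.86 * c, 2),
        tr.PollutantSpec("X", 0.1 * c, tr.fixed(1.86)))
    assert scaled == pytest.approx(base, rel=1e-9)


@given(st.permutations([0.06, 0.08, 0.10, 0.12, 0.2]))
def test_summary_permutation_invariant(vals):
    data = _table([
        {"sample_id": f"S{k}", "pollutant": "X", "concentration_mg_L": c}
        for k, c in enumerate(vals)
    ])
    s = summarize_pollutant(data, "X")
    assert (s.mean, s.sd, s.minimum, s.maximum) == pytest.approx(
        (0.112, np.std([0.06, 0.08, 0.10, 0.12, 0.2], ddof=1), 0.06, 0.2))
    assert s.minimum <= s.mean <= s.maximum
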