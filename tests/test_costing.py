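"""Unit costs, CPI adjustment and phase-based treatment accrual."""

import numpy as np
import pytest

from mammosim import default_config
from mammosim.config import ConfigError, CostConfig
from mammosim.costing import (accrue_intervals, cpi_adjust, screen_cost,
                              treatment_stream, workup_cost)


@pytest.fixture
def costs_2009():
    """Phase table taken as already-2009 EUR (no CPI factor on treatment)."""
    c = CostConfig()
    c.treatment_costs_are_2005 = False
    return c


def test_screen_costs():
    costs = CostConfig()
    assert screen_cost("screen_film", costs) == 39.29
    assert screen_cost("digital", costs) == 42.28
    assert screen_cost("digital", costs) - screen_cost("screen_film", costs) \
        == pytest.approx(2.99)
    with pytest.raises(KeyError):
        screen_cost("mri", costs)


def test_workup_cost_examples():
    costs = CostConfig()
    assert workup_cost(("fnac",), costs, "digital") == pytest.approx(303.25)
    assert workup_cost((), costs, "digital") == 0.0
    assert workup_cost(("ultrasound", "fnac"), costs, "digital") == pytest.approx(319.94)
    # confirmatory mammogram priced as the technique's screening mammogram
    assert workup_cost(("additional_mammogram",), costs, "screen_film") \
        == pytest.approx(39.29)
    with pytest.raises(KeyError):
        workup_cost(("mri",), costs, "digital")


def test_cpi_adjust():
    assert cpi_adjust(100.0) == pytest.approx(107.90)
    assert cpi_adjust(0.0) == 0.0
    assert cpi_adjust(2236.92) == pytest.approx(2413.64, abs=0.005)
    with pytest.raises(ValueError):
        cpi_adjust(-1.0)


def test_treatment_stream_stage_ii_full_course(costs_2009):
    """Stage II, no recurrence, survives: 10.62x2,236.92 + 110.38x577.35."""
    stream = treatment_stream("II", 0.0, 50.0, 20, costs_2009)
    assert stream.sum() == pytest.approx(87_483.98, abs=0.01)


def test_treatment_stream_cis_full_course(costs_2009):
    stream = treatment_stream("CIS", 0.0, 50.0, 20, costs_2009)
    assert stream.sum() == pytest.approx(26_760.46, abs=0.01)


def test_treatment_stream_stage_iv_lifetime(costs_2009):
    """Stage IV pays the advanced rate from detection to death: 10 months."""
    stream = treatment_stream("IV", 0.0, 10.0 / 12.0, 20, costs_2009)
    assert stream.sum() == pytest.approx(34_387.10, abs=0.01)


def test_treatment_stream_death_at_detection(costs_2009):
    stream = treatment_stream("II", 5.0, 5.0, 20, costs_2009)
    assert stream.sum() == 0.0


def test_treatment_stream_truncates_at_horizon(costs_2009):
    full = treatment_stream("II", 0.0, 50.0, 20, costs_2009)
    late = treatment_stream("II", 15.0, 50.0, 20, costs_2009)
    assert late.sum() < full.sum()
    assert np.all(late[:15] == 0.0)


def test_treatment_stream_cpi_scaling():
    c2005 = CostConfig()  # default: table is 2005 EUR, CPI applied
    c2009 = CostConfig()
    c2009.treatment_costs_are_2005 = False
    s1 = treatment_stream("II", 0.0, 50.0, 20, c2005)
    s2 = treatment_stream("II", 0.0, 50.0, 20, c2009)
    assert s1.sum() == pytest.approx(1.079 * s2.sum(), rel=1e-9)


def test_treatment_stream_with_recurrence(costs_2009):
    """Forced recurrence: follow-up truncates and the advanced phase runs on."""
    # u_recur=0 forces recurrence; u_recur_time=0.5 puts it mid-follow-up
    stream = treatment_stream("III", 0.0, 30.0, 20, costs_2009,
                              u_recur=0.0, u_recur_time=0.5)
    init_m, fu_m = 11.11, 109.89
    end_init = init_m / 12.0
    t_rec = end_init + 0.5 * (fu_m / 12.0)
    expected = (init_m * 2236.92
                + 0.5 * fu_m * 737.65
                + (20.0 - t_rec) * 12.0 * 3438.71)
    assert stream.sum() == pytest.approx(expected, rel=1e-9)


def test_treatment_rejects_death_before_detection(costs_2009):
    with pytest.raises(ValueError):
        treatment_stream("II", 5.0, 4.0, 20, costs_2009)


def test_accrue_intervals_maps_to_calendar_years():
    out = accrue_intervals(np.array([0.5]), np.array([2.25]), np.array([120.0]), 20)
    # 120/month = 1440/year over 1.75 years split 0.5 / 1.0 / 0.25
    np.testing.assert_allclose(out[:3], [720.0, 1440.0, 360.0])
    assert out[3:].sum() == 0.0


def test_followup_duration_identity_enforced():
    """Table rule: follow-up = 120 - (initial - 1) months, per stage."""
    cfg = default_config()
    for s in ("CIS", "I", "II", "III"):
        row = cfg.costs.treatment[s]
        assert row["followup_months"] == pytest.approx(
            120.0 - (row["initial_months"] - 1.0), abs=0.01)
    cfg.costs.treatment["II"]["followup_months"] = 100.0
    with pytest.raises(ConfigError):
        cfg.costs.validate()


def test_cost_stream_additivity_and_nonnegativity(small_run):
    for t in ("digital", "screen_film"):
        cs = small_run.arms[t].cost_stream
        np.testing.assert_allclose(
            cs.overall, cs.screening + cs.additional_tests + cs.treatment)
        assert np.all(cs.screening >= 0) and np.all(cs.treatment >= 0)
        assert len(cs.years) == 20 and cs.years[0] == 2010
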