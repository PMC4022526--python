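"""Onset, sojourn, stage assignment and survival stand-in."""

import numpy as np
import pytest
from scipy import stats

from mammosim import default_config, sample_parameter_draw
from mammosim.fixtures import IncidenceModel
from mammosim.natural_history import (assign_stage, assign_stage_vec,
                                      sample_bc_survival, sample_onset,
                                      sojourn_time, stage_medians,
                                      survival_quantile)


def _flat_incidence(rate: float, min_age: float = 0.0) -> IncidenceModel:
    ages = np.arange(0.0, 121.0)
    return IncidenceModel(ages, np.full(len(ages), rate), min_age=min_age)


@pytest.mark.parametrize("age,expected", [(40.0, 2.0), (35.0, 2.0),
                                          (52.0, 4.0), (50.0, 4.0),
                                          (45.0, 3.0), (47.5, 3.5)])
def test_sojourn_interpolation(age, expected):
    assert sojourn_time(age) == pytest.approx(expected)


def test_sojourn_rejects_nonpositive_age():
    with pytest.raises(ValueError):
        sojourn_time(-1.0)


def test_onset_zero_hazard_never_occurs(rng):
    inc = _flat_incidence(0.0)
    onset = sample_onset(np.full(100, 50.0), np.full(100, 100.0), inc, rng=rng)
    assert np.all(np.isnan(onset))


def test_onset_constant_hazard_is_exponential(rng):
    lam = 0.1
    inc = _flat_incidence(lam)
    onset = sample_onset(np.zeros(10_000), np.full(10_000, 1e6), inc, rng=rng)
    waits = onset[~np.isnan(onset)]
    assert len(waits) == 10_000  # no censoring at this death age
    ks = stats.kstest(waits, "expon", args=(0, 1 / lam))
    assert ks.pvalue > 0.01


def test_onset_censored_by_death(rng):
    inc = _flat_incidence(0.05)
    death = np.full(5000, 60.0)
    onset = sample_onset(np.full(5000, 50.0), death, inc, rng=rng)
    valid = onset[~np.isnan(onset)]
    assert np.all(valid < 60.0)
    assert np.all(valid > 50.0)


def test_assign_stage_contexts():
    cfg = default_config()
    draw = sample_parameter_draw(cfg, np.random.default_rng(0), psa_mode="mean")
    # degenerate vector: always CIS
    draw.stage_dist[("screen", "initial", "digital")] = np.array([1.0, 0, 0, 0, 0])
    for u in (0.0, 0.5, 0.999):
        assert assign_stage("screen", "initial", "digital", draw, u) == 0
    # clinical stage identical across techniques for the same random number
    for u in (0.05, 0.4, 0.9):
        s_dm = assign_stage("clinical", "successive", "digital", draw, u)
        s_sf = assign_stage("clinical", "successive", "screen_film", draw, u)
        assert s_dm == s_sf
    with pytest.raises(KeyError):
        assign_stage("screen", "initial", "mri", draw, 0.5)


def test_screen_detected_stage_frequencies(rng):
    """Sampled digital screen-detected stages match the program proportions."""
    cfg = default_config()
    draw = sample_parameter_draw(cfg, np.random.default_rng(0), psa_mode="mean")
    vec = np.asarray(draw.stage_dist[("screen", "successive", "digital")])
    u = rng.random(100_000)
    idx = assign_stage_vec(vec, u)
    freq = np.bincount(idx, minlength=5) / len(u)
    target = np.array([21.4, 41.3, 29.4, 7.4, 0.4])
    np.testing.assert_allclose(100 * freq, target / target.sum() * 100, atol=1.0)


def test_survival_median_oracle(rng):
    """Stage IV exponential stand-in: empirical median ~3 years."""
    cfg = default_config()
    med = stage_medians(cfg.natural_history)
    t = survival_quantile(np.full(10_000, 4), rng.random(10_000), med)
    assert np.median(t) == pytest.approx(3.0, abs=0.2)


def test_survival_stochastic_dominance(rng):
    """Stage I survival dominates stage III pointwise (shared quantiles)."""
    cfg = default_config()
    med = stage_medians(cfg.natural_history)
    u = rng.random(10_000)
    t1 = survival_quantile(np.full(10_000, 1), u, med)
    t3 = survival_quantile(np.full(10_000, 3), u, med)
    assert np.all(t1 >= t3)
    for horizon in (2.0, 5.0, 10.0, 20.0):
        assert (t1 > horizon).mean() >= (t3 > horizon).mean()


def test_bc_death_after_detection():
    cfg = default_config()
    rng = np.random.default_rng(4)
    for stage in ("CIS", "I", "II", "III", "IV"):
        assert sample_bc_survival(stage, 62.5, rng, cfg) > 62.5


def test_stage_medians_must_be_ordered():
    cfg = default_config()
    cfg.natural_history.survival_median_years["III"] = 500.0
    with pytest.raises(ValueError):
        stage_medians(cfg.natural_history)
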