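"""Replication orchestration, aggregation, pairing and PSA scenarios."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mammosim import aggregate, classify_run, default_config, run_replication
from mammosim.budget import (DM_BETTER, INTERMEDIATE, SFM_BETTER, RunResult,
                             classify_results, run_replications,
                             summarize_by_group)
from mammosim.costing import CostStream
from mammosim.engine import ArmResult
from mammosim.fixtures import Fixtures


def _fake_result(rep: int, diff: float) -> RunResult:
    """Paired result whose yearly overall difference is `diff` (treatment)."""
    arms = {}
    for t, extra in (("digital", 0.0), ("screen_film", diff)):
        cs = CostStream.zeros(2010, 20)
        cs.treatment += 100.0 + extra
        arms[t] = ArmResult(technique=t, counters={}, cost_stream=cs, rates={})
    return RunResult(replication=rep, seed=rep, arms=arms)


def test_aggregate_hand_computed_ci():
    """Two replications with yearly diffs 0 and 10: mean 5 +- 1.96*SD/sqrt(2)."""
    impact = aggregate([_fake_result(0, 0.0), _fake_result(1, 10.0)])
    sd = np.std([0.0, 10.0], ddof=1)  # 7.0711
    half = 1.96 * sd / np.sqrt(2)
    assert impact.mean["overall"][0] == pytest.approx(5.0)
    assert impact.ci_low["overall"][0] == pytest.approx(5.0 - half, abs=1e-9)
    assert impact.ci_high["overall"][0] == pytest.approx(5.0 + half, abs=1e-9)


def test_aggregate_identical_runs_zero_width_ci():
    impact = aggregate([_fake_result(i, 4.0) for i in range(5)])
    assert impact.ci_low["overall"][3] == impact.ci_high["overall"][3] == \
        pytest.approx(4.0)


def test_aggregate_requires_two_replications():
    with pytest.raises(ValueError):
        aggregate([_fake_result(0, 1.0)])


def test_replication_deterministic(small_config, small_fixtures):
    r1 = run_replication(small_config, 77, fixtures=small_fixtures)
    r2 = run_replication(small_config, 77, fixtures=small_fixtures)
    for t in ("digital", "screen_film"):
        assert r1.arms[t].counters == r2.arms[t].counters
        np.testing.assert_array_equal(r1.cost_matrix(t), r2.cost_matrix(t))


def test_pairing_identical_parameters_zero_difference(small_config, small_fixtures):
    """With identical technique parameters both arms are bit-identical."""
    cfg = copy.deepcopy(small_config)
    cfg.screening.specificity["digital"] = dict(cfg.screening.specificity["screen_film"])
    cfg.stages.screen["digital"] = list(cfg.stages.screen["screen_film"])
    cfg.costs.screen_cost["digital"] = cfg.costs.screen_cost["screen_film"]
    cfg.workup.recalls["digital"] = cfg.workup.recalls["screen_film"]
    cfg.workup.counts["digital"] = dict(cfg.workup.counts["screen_film"])
    res = run_replication(cfg, 31, fixtures=small_fixtures, psa_mode="mean")
    np.testing.assert_array_equal(res.difference_matrix(), 0.0)
    assert res.arms["digital"].counters == res.arms["screen_film"].counters


def test_overall_difference_decomposes(small_run):
    d = small_run.difference_matrix()
    np.testing.assert_allclose(d[:, 0], d[:, 1] + d[:, 2] + d[:, 3], rtol=1e-12)


def test_digital_recalls_fewer_with_mean_parameters(small_config, small_fixtures):
    """Higher digital specificity modes imply fewer digital recalls."""
    wins = 0
    for seed in range(8):
        r = run_replication(small_config, 1000 + seed, fixtures=small_fixtures,
                            psa_mode="mean")
        wins += (r.arms["digital"].counters["recalls"]
                 < r.arms["screen_film"].counters["recalls"])
    assert wins == 8


def test_replications_independent_across_seeds(small_config, small_fixtures):
    """Counter-derived seeds: no autocorrelation in yearly overall differences."""
    cfg = default_config(scale=0.01)
    fx = Fixtures.from_config(cfg)
    results = run_replications(cfg, 120, master_seed=5, fixtures=fx)
    series = np.array([r.difference_matrix()[19, 0] for r in results])
    x, y = series[:-1] - series.mean(), series[1:] - series.mean()
    r1 = np.sum(x * y) / np.sum((series - series.mean()) ** 2)
    assert abs(r1) < 0.2  # lag-1 autocorrelation consistent with independence


@pytest.mark.parametrize("rates,expected", [
    ((6.9, 6.0, 5.5, 6.5), DM_BETTER),     # DM detects more, recalls less
    ((6.4, 6.4, 6.1, 6.1), INTERMEDIATE),  # both similar
    ((7.0, 6.4, 6.6, 6.0), INTERMEDIATE),  # opposite-direction split
    ((6.0, 6.9, 6.5, 5.5), SFM_BETTER),
    ((6.5, 6.0, 6.0, 6.0), DM_BETTER),     # boundary 0.5 counts as better
    ((6.0, 6.5, 6.0, 6.0), SFM_BETTER),
    ((6.9, 6.0, 6.0, 6.1), DM_BETTER),     # better detection, similar recall
])
def test_classify_run(rates, expected):
    assert classify_run(*rates) == expected


def test_classify_rejects_negative_rates():
    with pytest.raises(ValueError):
        classify_run(-1.0, 6.0, 6.0, 6.0)


@given(st.tuples(*[st.floats(min_value=0, max_value=20) for _ in range(4)]))
@settings(max_examples=300, deadline=None, derandomize=True)
def test_classify_exhaustive_and_exclusive(rates):
    assert classify_run(*rates) in (DM_BETTER, SFM_BETTER, INTERMEDIATE)


def test_group_partition_and_nonempty(small_config, small_fixtures):
    cfg = default_config(scale=0.02)
    fx = Fixtures.from_config(cfg)
    results = run_replications(cfg, 60, master_seed=17, fixtures=fx)
    labels = classify_results(results)
    summary = summarize_by_group(results)
    assert sum(info["n"] for info in summary.values()) == len(results)
    # the configured Beta spreads produce all three scenario groups
    assert all(info["n"] > 0 for info in summary.values())
    assert set(labels) <= {DM_BETTER, SFM_BETTER, INTERMEDIATE}


def test_identical_parameter_runs_all_intermediate(small_config, small_fixtures):
    cfg = copy.deepcopy(small_config)
    cfg.screening.specificity["digital"] = dict(cfg.screening.specificity["screen_film"])
    results = [run_replication(cfg, s, fixtures=small_fixtures, psa_mode="mean")
               for s in (1, 2)]
    assert classify_results(results) == [INTERMEDIATE, INTERMEDIATE]
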