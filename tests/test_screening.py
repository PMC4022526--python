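"""Participation, screen outcome classification and work-up assignment."""

import numpy as np
import pytest

from mammosim import default_config, sample_parameter_draw
from mammosim.screening import (build_participation_profile,
                                decompose_workup_margins,
                                false_negative_followup, perform_screen,
                                sample_workup, workup_combo_margins)


def test_profile_all_attend_when_certain():
    rng = np.random.default_rng(0)
    profile = build_participation_profile(1.0, 1.0, rng)
    assert profile.all() and len(profile) == 10


def test_profile_rejects_more_than_ten_rounds():
    with pytest.raises(ValueError):
        build_participation_profile(0.8, 0.8, np.random.default_rng(0), n_rounds=11)


def test_profile_first_round_frequency():
    """First-invitation attendance matches the initial participation rate."""
    rng = np.random.default_rng(1)
    first = np.array([build_participation_profile(0.787, 0.832, rng)[0]
                      for _ in range(100_000)])
    assert first.mean() == pytest.approx(0.787, abs=0.004)


def test_sticky_profile_gates_all_rounds():
    rng = np.random.default_rng(2)
    for _ in range(200):
        p = build_participation_profile(0.5, 0.9, rng, model="sticky")
        if not p[0]:
            assert not p.any()


def test_perform_screen_classification():
    assert perform_screen(True, 1.0, 0.9, u=0.99) == "TP"
    assert perform_screen(True, 0.5, 0.9, u=0.7) == "FN"
    assert perform_screen(False, 0.9, 0.954, u=0.96) == "FP"
    assert perform_screen(False, 0.9, 0.954, u=0.3) == "TN"


def test_fp_frequency_binomial_oracle(rng):
    """FP frequency in cancer-free screens ~ Binomial(n, 1-specificity)."""
    spec = 0.954
    n = 100_000
    u = rng.random(n)
    fp_rate = np.mean([perform_screen(False, 0.87, spec, x) == "FP"
                       for x in u[:5000]])
    sd5k = np.sqrt((1 - spec) * spec / 5000)
    assert abs(fp_rate - (1 - spec)) < 3 * sd5k
    fp_rate = np.mean(u > spec)
    sd = np.sqrt((1 - spec) * spec / n)
    assert abs(fp_rate - (1 - spec)) < 3 * sd


def test_fp_monotone_in_specificity_under_crn(rng):
    u = rng.random(50_000)
    fp_low = np.mean(u > 0.954)
    fp_high = np.mean(u > 0.958)
    assert fp_high < fp_low


def test_false_negative_followup_ordering():
    assert false_negative_followup(61.0, 62.0) == "interval"
    assert false_negative_followup(63.0, 62.0) == "rescreen"
    assert false_negative_followup(61.0, None) == "interval"


@pytest.mark.parametrize("technique", ["digital", "screen_film"])
def test_workup_decomposition_reproduces_margins(technique):
    cfg = default_config()
    margins = cfg.workup.margins(technique)
    combos, probs = decompose_workup_margins(margins)
    assert all(len(c) > 0 for c in combos)  # every recalled woman gets a test
    realized = workup_combo_margins(combos, probs)
    for test, target in margins.items():
        assert realized[test] == pytest.approx(target, abs=0.01)


def test_workup_headline_combinations():
    """One ultrasound scan ~30% for digital; ultrasound+FNAC ~22% screen-film."""
    cfg = default_config()
    combos, probs = decompose_workup_margins(cfg.workup.margins("digital"))
    us_only = sum(p for c, p in zip(combos, probs) if set(c) == {"ultrasound"})
    assert us_only == pytest.approx(0.30, abs=0.05)
    combos, probs = decompose_workup_margins(cfg.workup.margins("screen_film"))
    us_fnac = sum(p for c, p in zip(combos, probs)
                  if set(c) == {"ultrasound", "fnac"})
    assert us_fnac == pytest.approx(0.22, abs=0.05)


def test_workup_decomposition_rejects_impossible_margins():
    bad = {"additional_mammogram": 0.1, "ultrasound": 0.2, "fnac": 0.3,
           "core_biopsy": 0.2, "open_biopsy": 0.1}  # ultrasound < invasive sum
    with pytest.raises(ValueError):
        decompose_workup_margins(bad)


def test_sample_workup_degenerate():
    cfg = default_config()
    draw = sample_parameter_draw(cfg, np.random.default_rng(0), psa_mode="mean")
    draw.workup_dist[("digital", "initial")] = ([("ultrasound",)], np.array([1.0]))
    for u in (0.0, 0.5, 0.99):
        assert sample_workup("digital", "initial", draw, u) == ("ultrasound",)


def test_screen_outcome_identities(small_run):
    """screens = TP+FP+TN+FN and recall rate = FP rate + detection rate."""
    for t in ("digital", "screen_film"):
        c = small_run.arms[t].counters
        r = small_run.arms[t].rates
        assert c["screens"] == c["tp"] + c["fp"] + c["tn"] + c["fn"]
        assert c["recalls"] == c["tp"] + c["fp"]
        assert r["recall_rate_pct"] == pytest.approx(
            r["fp_rate_pct"] + r["detection_rate_pct"], abs=1e-9)
        assert c["fp"] == c["fp_initial"] + c["fp_successive"]
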