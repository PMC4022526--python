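"""Vectorized paired-arm simulation engine.

One replication simulates the same cohort of women twice, once per
mammography technique, consuming identical pre-drawn random numbers
(common random numbers): natural histories, participation profiles and
per-round uniforms are shared, so the arms differ only through the
technique parameters of the replication's ParameterDraw. Because a round's
outcome never influences the random numbers of later rounds (only whether
they are used), the whole event timeline can be computed with array
operations instead of an explicit event queue, which is what makes
full-scale replications take seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config, ROUND_TYPES, STAGES
from .costing import (CostStream, accrue_intervals, treatment_intervals,
                      workup_combo_costs)
from .fixtures import Fixtures
from .natural_history import (sample_onset, sojourn_time_config, stage_medians,
                              survival_quantile)
from .population import Cohort, build_cohort
from .psa import ParameterDraw


@dataclass
class SharedRandoms:
    """All random numbers of one replication, drawn once and used by both arms."""

    u_gate: np.ndarray       # historical participation gate (initial population)
    u_part: np.ndarray       # (n, K) attendance uniforms
    u_screen: np.ndarray     # (n, K) screen outcome uniforms
    u_workup: np.ndarray     # (n, K) work-up combination uniforms
    u_stage: np.ndarray      # stage at detection
    u_surv: np.ndarray       # breast-cancer survival quantile
    u_recur: np.ndarray      # recurrence indicator
    u_recur_time: np.ndarray # recurrence timing within follow-up

    @classmethod
    def draw(cls, n: int, max_rounds: int, rng: np.random.Generator) -> "SharedRandoms":
        return cls(
            u_gate=rng.random(n),
            u_part=rng.random((n, max_rounds)),
            u_screen=rng.random((n, max_rounds)),
            u_workup=rng.random((n, max_rounds)),
            u_stage=rng.random(n),
            u_surv=rng.random(n),
            u_recur=rng.random(n),
            u_recur_time=rng.random(n),
        )


@dataclass
class NaturalHistories:
    """Per-woman cancer timelines, shared by both arms until detection."""

    onset_age: np.ndarray          # nan if no onset
    sojourn_years: np.ndarray
    clinical_onset_age: np.ndarray

    @classmethod
    def sample(cls, cohort: Cohort, fixtures: Fixtures, config: Config,
               rng: np.random.Generator) -> "NaturalHistories":
        onset = sample_onset(cohort.entry_age, cohort.death_age_other,
                             fixtures.incidence, rng=rng)
        onset = np.atleast_1d(onset)
        soj = np.where(np.isnan(onset), np.nan,
                       sojourn_time_config(onset, config.natural_history))
        return cls(onset, soj, onset + soj)


def participation_matrix(cohort: Cohort, draw: ParameterDraw, shared: SharedRandoms,
                         config: Config) -> np.ndarray:
    """Attendance indicators per woman and invitation (shared by both arms)."""
    p_init = draw.participation.p_initial
    p_succ = draw.participation.p_successive
    model = config.participation.model
    att = shared.u_part < p_succ
    new = ~cohort.attended_before
    if model == "independent":
        att[new, 0] = shared.u_part[new, 0] < p_init
        return att
    if model != "sticky":
        raise ValueError(f"unknown participation model {model!r}")
    gate = np.where(new, shared.u_part[:, 0] < p_init, shared.u_gate < p_init)
    att[new, 0] = True  # gate itself decides first attendance for new women
    return att & gate[:, None]


@dataclass
class ArmResult:
    technique: str
    counters: dict
    cost_stream: CostStream
    rates: dict
    #: per-woman diagnosis arrays for debugging/event export
    detection: dict = field(default_factory=dict)

    def diagnosis_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.detection)


def simulate_arm(cohort: Cohort, histories: NaturalHistories, draw: ParameterDraw,
                 shared: SharedRandoms, config: Config, technique: str) -> ArmResult:
    pop = config.population
    K = pop.max_rounds
    horizon = float(pop.horizon_years)
    n = cohort.n
    k = np.arange(K)

    T = cohort.first_screen_time[:, None] + 2.0 * k[None, :]
    Age = cohort.first_screen_age[:, None] + 2.0 * k[None, :]
    death_oc_time = cohort.death_time_other()

    invited = (Age < pop.exit_age) & (T < horizon)
    profile = participation_matrix(cohort, draw, shared, config)
    attended = profile & invited & (T < death_oc_time[:, None])

    # a woman's first attended invitation is her initial screen, unless she
    # was already screened before the simulation started
    first_attended = attended & (np.cumsum(attended, axis=1) == 1)
    is_initial = first_attended & ~cohort.attended_before[:, None]

    params = draw.techniques[technique]
    sens = params.sensitivity
    spec_k = np.where(is_initial, params.specificity_initial, params.specificity_successive)

    onset_age = histories.onset_age
    clin_age = histories.clinical_onset_age
    with np.errstate(invalid="ignore"):
        pre = attended & (Age >= onset_age[:, None]) & (Age < clin_age[:, None])
        has_onset = ~np.isnan(onset_age)
        free = attended & (~has_onset[:, None] | (Age < np.where(has_onset, onset_age, np.inf)[:, None]))

    pos_pre = pre & (shared.u_screen < sens)
    has_tp = pos_pre.any(axis=1)
    k_star = np.argmax(pos_pre, axis=1)
    rows = np.arange(n)
    det_screen_time = np.where(has_tp, T[rows, k_star], np.inf)

    clin_time = cohort.entry_time + (clin_age - cohort.entry_age)
    # last attended screen before clinical surfacing (for follow-up rules)
    before_clin = attended & (T < np.where(np.isnan(clin_time), -np.inf, clin_time)[:, None])
    any_before = before_clin.any(axis=1)
    last_k = K - 1 - np.argmax(before_clin[:, ::-1], axis=1)
    last_T = np.where(any_before, T[rows, last_k], -np.inf)

    # women past the exit age are followed only if the cancer surfaces within
    # the interval-cancer window after their last mammogram
    window = config.screening.interval_window_years
    followed = (clin_age < pop.exit_age) | (clin_time - last_T <= window)
    clin_det = (has_onset & ~has_tp & followed
                & (clin_time < np.minimum(horizon, death_oc_time)))

    det_time = np.where(has_tp, det_screen_time, np.where(clin_det, clin_time, np.inf))

    eff = attended & (T <= det_time[:, None])
    tp = np.zeros_like(eff)
    tp[rows[has_tp], k_star[has_tp]] = True
    fn = pre & ~pos_pre & eff
    fp = free & (shared.u_screen > spec_k) & eff
    tn = free & ~(shared.u_screen > spec_k) & eff

    # ---- screening and work-up costs -------------------------------------
    years = np.floor(T).astype(int)
    hy = pop.horizon_years
    stream = CostStream.zeros(pop.start_year, hy)

    y_eff = years[eff]
    np.add.at(stream.screening, y_eff, params.cost_per_screen)

    recall = tp | fp
    combo_cost = {}
    combo_cum = {}
    for r in ROUND_TYPES:
        combos, probs = draw.workup_dist[(technique, r)]
        combo_cost[r] = workup_combo_costs(combos, config.costs, technique)
        combo_cum[r] = np.cumsum(probs)
    for r, is_init_flag in (("initial", True), ("successive", False)):
        mask = recall & (is_initial == is_init_flag)
        if not mask.any():
            continue
        u = shared.u_workup[mask]
        idx = np.clip(np.searchsorted(combo_cum[r], u, side="right"),
                      0, len(combo_cost[r]) - 1)
        np.add.at(stream.additional_tests, years[mask], combo_cost[r][idx])

    # ---- detection, stage, survival, treatment ---------------------------
    diagnosed = has_tp | clin_det
    det_age = cohort.entry_age + (det_time - cohort.entry_time)

    stage = np.full(n, -1)
    screen_init = np.zeros(n, dtype=bool)
    screen_init[has_tp] = is_initial[rows[has_tp], k_star[has_tp]]
    for setting, sel in (("screen", has_tp), ("clinical", clin_det)):
        if not sel.any():
            continue
        if setting == "screen":
            for r, flag in (("initial", True), ("successive", False)):
                sub = sel & (screen_init == flag)
                if sub.any():
                    vec = np.cumsum(draw.stage_dist[("screen", r, technique)])
                    stage[sub] = np.clip(np.searchsorted(vec, shared.u_stage[sub],
                                                         side="right"), 0, 4)
        else:
            vec = np.cumsum(draw.stage_dist[("clinical", "successive", technique)])
            stage[sel] = np.clip(np.searchsorted(vec, shared.u_stage[sel],
                                                 side="right"), 0, 4)

    medians = stage_medians(config.natural_history)
    bc_death_time = np.full(n, np.inf)
    d = diagnosed
    bc_death_time[d] = det_time[d] + survival_quantile(stage[d], shared.u_surv[d], medians)
    death_time_final = np.minimum(death_oc_time, bc_death_time)
    bc_death = diagnosed & (bc_death_time < death_oc_time)

    if d.any():
        s, e, m = treatment_intervals(stage[d], det_time[d], death_time_final[d],
                                      shared.u_recur[d], shared.u_recur_time[d],
                                      config.costs)
        stream.treatment += accrue_intervals(s, e, m, hy)

    # ---- counters --------------------------------------------------------
    last_is_fn = any_before & fn[rows, np.clip(last_k, 0, K - 1)]
    last_is_tn = any_before & tn[rows, np.clip(last_k, 0, K - 1)]
    interval_window_hit = clin_det & any_before & (clin_time - last_T <= window)
    fn_interval = clin_det & last_is_fn
    true_interval = interval_window_hit & last_is_tn & ~fn_interval
    interval = fn_interval | true_interval
    clinical_other = clin_det & ~interval

    def stage_counts(sel: np.ndarray) -> dict:
        return {s: int(np.sum(stage[sel] == i)) for i, s in enumerate(STAGES)}

    n_screens = int(eff.sum())
    n_initial = int((eff & is_initial).sum())
    n_tp = int(has_tp.sum())
    n_fp = int(fp.sum())
    counters = {
        "invited_women": n,
        "screens": n_screens,
        "screens_initial": n_initial,
        "screens_successive": n_screens - n_initial,
        "recalls": n_tp + n_fp,
        "tp": n_tp,
        "fp": n_fp,
        "fp_initial": int((fp & is_initial).sum()),
        "fp_successive": int((fp & ~is_initial).sum()),
        "fn": int(fn.sum()),
        "tn": int(tn.sum()),
        "cancers_screen_detected": n_tp,
        "cancers_screen_by_stage": stage_counts(has_tp),
        "cancers_clinical": int(clin_det.sum()),
        "cancers_clinical_by_stage": stage_counts(clin_det),
        "interval_cancers": int(interval.sum()),
        "interval_false_negative": int(fn_interval.sum()),
        "interval_true": int(true_interval.sum()),
        "clinical_nonscreening": int(clinical_other.sum()),
        "bc_deaths": int((bc_death & (bc_death_time < horizon)).sum()),
        "bc_deaths_by_stage": stage_counts(bc_death & (bc_death_time < horizon)),
    }
    rates = {
        "recall_rate_pct": 100.0 * counters["recalls"] / n_screens if n_screens else 0.0,
        "detection_rate_pct": 100.0 * n_tp / n_screens if n_screens else 0.0,
        "detection_rate_per_1000": 1000.0 * n_tp / n_screens if n_screens else 0.0,
        "fp_rate_pct": 100.0 * n_fp / n_screens if n_screens else 0.0,
        "fp_rate_initial_pct": (100.0 * counters["fp_initial"] / n_initial
                                if n_initial else 0.0),
        "fp_rate_successive_pct": (100.0 * counters["fp_successive"] / (n_screens - n_initial)
                                   if n_screens > n_initial else 0.0),
        "initial_share_pct": 100.0 * n_initial / n_screens if n_screens else 0.0,
    }
    detection = {
        "diagnosed": diagnosed,
        "setting": np.where(has_tp, "screen", np.where(clin_det, "clinical", "")),
        "det_time": det_time,
        "stage": np.where(diagnosed, np.array(list(STAGES) + [""])[np.clip(stage, 0, 4)], ""),
        "bc_death_time": bc_death_time,
    }
    return ArmResult(technique=technique, counters=counters, cost_stream=stream,
                     rates=rates, detection=detection)


def simulate_replication(config: Config, fixtures: Fixtures, draw: ParameterDraw,
                         rng: np.random.Generator) -> dict:
    """Build one shared cohort and run both arms on it."""
    cohort = build_cohort(config, fixtures, rng)
    histories = NaturalHistories.sample(cohort, fixtures, config, rng)
    shared = SharedRandoms.draw(cohort.n, config.population.max_rounds, rng)
    return {t: simulate_arm(cohort, histories, draw, shared, config, t)
            for t in ("digital", "screen_film")}
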