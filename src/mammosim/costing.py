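"""Cost accrual: screening, additional (work-up) tests, and treatment.

All costs are undiscounted 2009 EUR from the payer's perspective. Screening
and work-up events are priced at their unit costs in the calendar year they
occur; treatment is a monthly accrual determined by stage and phase (initial,
follow-up, advanced) that runs in continuous time (1/12-year months) and is
apportioned to calendar years by position, truncated at death and at the
simulation horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config, CostConfig, STAGES, TECHNIQUES

MONTH = 1.0 / 12.0


def cpi_adjust(amount: float, rate: float = 0.079):
    """Inflate a 2005 amount to 2009 EUR with the cumulative CPI."""
    a = np.asarray(amount, dtype=float)
    if np.any(a < 0):
        raise ValueError("amount must be >= 0")
    out = a * (1.0 + rate)
    return float(out) if np.isscalar(amount) else out


def screen_cost(technique: str, costs: CostConfig) -> float:
    """Cost of one screening (or diagnostic) mammogram for a technique."""
    if technique not in TECHNIQUES:
        raise KeyError(f"unknown technique {technique!r}")
    return costs.screen_cost[technique]


def workup_cost(combo, costs: CostConfig, technique: str) -> float:
    """Total unit cost of one work-up test combination.

    A confirmatory (additional) mammogram is priced at the technique's
    screening mammogram cost, which is assumed equal for diagnostic use.
    """
    total = 0.0
    for test in combo:
        if test == "additional_mammogram":
            total += screen_cost(technique, costs)
        elif test in costs.workup_unit_costs:
            total += costs.workup_unit_costs[test]
        else:
            raise KeyError(f"unknown work-up test {test!r}")
    return total


def workup_combo_costs(combos, costs: CostConfig, technique: str) -> np.ndarray:
    return np.array([workup_cost(c, costs, technique) for c in combos])


@dataclass
class CostStream:
    """Per-calendar-year accrual for one arm, split by category."""

    years: np.ndarray
    screening: np.ndarray
    additional_tests: np.ndarray
    treatment: np.ndarray

    @classmethod
    def zeros(cls, start_year: int, horizon_years: int) -> "CostStream":
        years = np.arange(start_year, start_year + horizon_years)
        z = np.zeros(horizon_years)
        return cls(years, z.copy(), z.copy(), z.copy())

    @property
    def overall(self) -> np.ndarray:
        return self.screening + self.additional_tests + self.treatment

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.years,
            "overall": self.overall,
            "screening": self.screening,
            "additional_tests": self.additional_tests,
            "treatment": self.treatment,
        })


def accrue_intervals(start: np.ndarray, end: np.ndarray, monthly_cost: np.ndarray,
                     horizon_years: int) -> np.ndarray:
    """Map constant-rate accrual intervals onto simulation years.

    Each interval (start, end) in simulation-year units accrues
    ``monthly_cost`` per 1/12-year month; the return is the per-year total,
    intervals clipped to [0, horizon).
    """
    s = np.minimum(np.maximum(np.asarray(start, dtype=float), 0.0), horizon_years)
    e = np.minimum(np.maximum(np.asarray(end, dtype=float), 0.0), horizon_years)
    rate = np.asarray(monthly_cost, dtype=float) * 12.0  # per year
    out = np.zeros(horizon_years)
    for y in range(horizon_years):
        overlap = np.clip(np.minimum(e, y + 1.0) - np.maximum(s, y), 0.0, None)
        out[y] = np.dot(overlap, rate)
    return out


def treatment_intervals(stage_idx: np.ndarray, detect_time: np.ndarray,
                        death_time: np.ndarray, u_recur: np.ndarray,
                        u_recur_time: np.ndarray, costs: CostConfig
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phase intervals (start, end, monthly cost) for a set of diagnosed women.

    Stages below IV: an initial phase, then follow-up to 10 years
    post-surgery; with the stage's recurrence probability, a recurrence time
    uniform between the end of the initial phase and the end of follow-up
    truncates the follow-up and starts the advanced phase, which runs for the
    rest of life. Stage IV enters the advanced phase at detection. Costs are
    CPI-adjusted to 2009 if the phase table is in 2005 EUR. Truncation at
    death (and later at the horizon) caps every phase.
    """
    stage_idx = np.asarray(stage_idx, dtype=int)
    t0 = np.asarray(detect_time, dtype=float)
    td = np.asarray(death_time, dtype=float)
    if np.any(td < t0 - 1e-12):
        raise ValueError("death before detection in treatment accrual")
    cpi = (1.0 + costs.cpi_rate) if costs.treatment_costs_are_2005 else 1.0

    rows = {s: costs.phase_row(s) for s in ("CIS", "I", "II", "III")}
    init_m = np.array([rows[s].initial_months for s in ("CIS", "I", "II", "III")] + [0.0])
    init_c = np.array([rows[s].initial_cost_month for s in ("CIS", "I", "II", "III")] + [0.0])
    fu_m = np.array([rows[s].followup_months for s in ("CIS", "I", "II", "III")] + [0.0])
    fu_c = np.array([rows[s].followup_cost_month for s in ("CIS", "I", "II", "III")] + [0.0])
    p_rec = np.array([rows[s].recurrence_prob for s in ("CIS", "I", "II", "III")] + [0.0])

    is_iv = stage_idx == 4
    end_init = t0 + init_m[stage_idx] * MONTH
    end_fu = end_init + fu_m[stage_idx] * MONTH

    recur = (np.asarray(u_recur) < p_rec[stage_idx]) & ~is_iv
    t_rec = end_init + np.asarray(u_recur_time) * (end_fu - end_init)

    starts, ends, monthly = [], [], []
    # initial phase (stages < IV)
    starts.append(np.where(is_iv, t0, t0))
    ends.append(np.where(is_iv, t0, np.minimum(end_init, td)))
    monthly.append(np.where(is_iv, 0.0, init_c[stage_idx] * cpi))
    # follow-up, truncated at recurrence
    fu_end = np.where(recur, np.minimum(t_rec, end_fu), end_fu)
    starts.append(end_init)
    ends.append(np.minimum(fu_end, td))
    monthly.append(np.where(is_iv, 0.0, fu_c[stage_idx] * cpi))
    # advanced phase: from detection (stage IV) or recurrence, for the lifetime
    adv_start = np.where(is_iv, t0, np.where(recur, t_rec, np.inf))
    starts.append(adv_start)
    ends.append(np.where(adv_start < np.inf, td, np.inf))
    monthly.append(np.full(len(t0), costs.advanced_cost_month * cpi))

    s = np.concatenate(starts)
    e = np.concatenate(ends)
    m = np.concatenate(monthly)
    keep = np.isfinite(s) & (e > s) & (m > 0)
    return s[keep], e[keep], m[keep]


def treatment_stream(stage, detect_time: float, death_time: float,
                     horizon_years: int, costs: CostConfig,
                     u_recur: float = 1.0, u_recur_time: float = 0.5) -> np.ndarray:
    """Per-year treatment accrual for a single diagnosed woman.

    ``u_recur``/``u_recur_time`` are the uniforms deciding recurrence and its
    timing (defaults: no recurrence). Returns one value per simulation year.
    """
    idx = STAGES.index(stage) if isinstance(stage, str) else int(stage)
    s, e, m = treatment_intervals(np.array([idx]), np.array([detect_time]),
                                  np.array([death_time]), np.array([u_recur]),
                                  np.array([u_recur_time]), costs)
    return accrue_intervals(s, e, m, horizon_years)
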