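"""Breast-cancer natural history: onset, sojourn, stage, survival.

Each woman has at most one cancer and no spontaneous remission: a pre-clinical
(asymptomatic but screen-detectable) onset age drawn from the age-specific
onset hazard, a deterministic age-dependent sojourn, and a clinical onset at
onset + sojourn. Stage is assigned at detection from the detection context's
distribution (there is no stage-progression clock), and breast-cancer survival
is an exponential stand-in with stage-specific medians.
"""

from __future__ import annotations

import numpy as np

from .config import Config, NaturalHistoryConfig, STAGES
from .fixtures import IncidenceModel

_LN2 = float(np.log(2.0))


def sample_onset(entry_age, death_age, incidence: IncidenceModel,
                 rng: np.random.Generator = None, u=None):
    """Pre-clinical onset age by inverse transform over the remaining lifetime.

    Returns nan where no onset occurs before death from other causes: the
    exponential quantile is compared against the cumulative onset hazard
    accrued between the entry age and the death age.
    """
    a0 = np.atleast_1d(np.asarray(entry_age, dtype=float))
    d = np.atleast_1d(np.asarray(death_age, dtype=float))
    if u is None:
        u = rng.random(size=len(a0))
    e = -np.log1p(-np.asarray(u))  # Exp(1) quantiles
    # hazard depends only on age: build one cumulative-hazard curve and invert
    grid = np.arange(0.0, 130.0 + 0.125, 0.125)
    h = incidence.hazard_at(grid)
    cumH = np.concatenate([[0.0], np.cumsum((h[1:] + h[:-1]) / 2 * np.diff(grid))])
    target = np.interp(a0, grid, cumH) + e
    out = np.interp(target, cumH, grid, right=np.inf)
    out[target > cumH[-1]] = np.nan  # no onset within the modeled ages
    out[~(out < d)] = np.nan         # censored by death from other causes
    out[~(out > a0)] = np.nan
    if np.ndim(entry_age) == 0 and len(out) == 1:
        return float(out[0])
    return out


def sojourn_time(onset_age):
    """Duration of the pre-clinical screen-detectable phase, in years.

    2 years at onset age 40 or below, 4 years at 50 or above, linear between
    the two anchors.
    """
    a = np.asarray(onset_age, dtype=float)
    if np.any(a <= 0):
        raise ValueError("onset age must be positive")
    s = np.interp(a, [40.0, 50.0], [2.0, 4.0])
    return float(s) if np.isscalar(onset_age) else s


def sojourn_time_config(onset_age, nh: NaturalHistoryConfig):
    a = np.asarray(onset_age, dtype=float)
    return np.interp(a, [nh.sojourn_age_young, nh.sojourn_age_old],
                     [nh.sojourn_years_young, nh.sojourn_years_old])


def assign_stage(setting: str, round_type: str, technique: str, draw,
                 rng_or_u) -> int:
    """Stage index (0=CIS .. 4=IV) for one detected cancer.

    Screen-detected cancers use the technique- and round-specific vector of
    the replication's ParameterDraw; clinically detected cancers (interval
    cancers, nonparticipants) use the shared clinical vector, so the same
    random number yields the same stage in both arms.
    """
    key = (setting, round_type, technique)
    if key not in draw.stage_dist:
        raise KeyError(f"unknown stage-distribution context {key}")
    vec = np.asarray(draw.stage_dist[key])
    u = rng_or_u.random() if isinstance(rng_or_u, np.random.Generator) else float(rng_or_u)
    return int(np.searchsorted(np.cumsum(vec), u, side="right").clip(0, 4))


def assign_stage_vec(vec: np.ndarray, u: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.cumsum(vec), u, side="right").clip(0, 4)


def survival_quantile(stage_idx, u, medians: np.ndarray):
    """Years from detection to breast-cancer death at quantile u.

    Exponential stand-in: t = -median/ln2 * log(1-u); the hazard ordering
    CIS < I < II < III < IV is inherited from the decreasing medians.
    """
    med = medians[np.asarray(stage_idx, dtype=int)]
    return -med / _LN2 * np.log1p(-np.asarray(u, dtype=float))


def sample_bc_survival(stage: str | int, age_at_detection: float,
                       rng: np.random.Generator, config: Config) -> float:
    """Breast-cancer death age for one woman (> detection age)."""
    medians = stage_medians(config.natural_history)
    idx = STAGES.index(stage) if isinstance(stage, str) else int(stage)
    t = float(survival_quantile(idx, rng.random(), medians))
    return age_at_detection + t


def stage_medians(nh: NaturalHistoryConfig) -> np.ndarray:
    med = np.array([nh.survival_median_years[s] for s in STAGES], dtype=float)
    if np.any(np.diff(med) >= 0):
        raise ValueError("survival medians must be strictly decreasing CIS > I > II > III > IV")
    return med
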