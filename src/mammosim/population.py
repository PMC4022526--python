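"""Dynamic target population: creation, biennial entry, death, exit at 70.

The cohort is held as a structure of arrays (one entry per woman) shared by
both simulation arms; ``Woman`` is a convenience view over one row for
inspection and debugging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Config
from .fixtures import Fixtures, LifeTable


@dataclass
class Woman:
    """One simulated individual (read-only view over the cohort arrays)."""

    id: int
    entry_time: float
    entry_age: float
    first_screen_time: float
    first_screen_age: float
    death_age_other: float
    attended_before: bool
    onset_age: float  # nan if no pre-clinical onset
    sojourn_years: float
    clinical_onset_age: float
    participation: np.ndarray


@dataclass
class Cohort:
    """All women of one replication (initial population plus entrants)."""

    entry_time: np.ndarray        # simulation years (0 = start)
    entry_age: np.ndarray
    first_screen_time: np.ndarray
    first_screen_age: np.ndarray
    death_age_other: np.ndarray   # all-cause death age (excluding breast cancer)
    attended_before: np.ndarray   # attended the program before simulation start
    is_entrant: np.ndarray

    @property
    def n(self) -> int:
        return len(self.entry_time)

    def woman(self, i: int, histories=None, participation=None) -> Woman:
        """Single-row view for inspection; optional timeline/profile arrays."""
        nan = float("nan")
        return Woman(
            id=i,
            entry_time=float(self.entry_time[i]),
            entry_age=float(self.entry_age[i]),
            first_screen_time=float(self.first_screen_time[i]),
            first_screen_age=float(self.first_screen_age[i]),
            death_age_other=float(self.death_age_other[i]),
            attended_before=bool(self.attended_before[i]),
            onset_age=float(histories.onset_age[i]) if histories else nan,
            sojourn_years=float(histories.sojourn_years[i]) if histories else nan,
            clinical_onset_age=(float(histories.clinical_onset_age[i])
                                if histories else nan),
            participation=participation[i] if participation is not None else None,
        )

    def death_time_other(self) -> np.ndarray:
        return self.entry_time + (self.death_age_other - self.entry_age)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "entry_time": self.entry_time,
            "entry_age": self.entry_age,
            "first_screen_time": self.first_screen_time,
            "death_age_other": self.death_age_other,
            "attended_before": self.attended_before,
            "is_entrant": self.is_entrant,
        })


def sample_death_other_causes(current_age, life_table: LifeTable,
                              rng: np.random.Generator, size: int | None = None):
    """Age at death from causes other than breast cancer.

    Inverse transform on the life table's piecewise-constant hazard,
    conditional on being alive at ``current_age``; always strictly greater
    than the current age, and exactly the year start where q = 1.
    """
    scalar = size is None and np.isscalar(current_age)
    ages = np.atleast_1d(np.asarray(current_age, dtype=float))
    if size is not None and len(ages) == 1:
        ages = np.repeat(ages, size)
    if np.any(ages >= life_table.terminal_age):
        raise ValueError("current age must be below the terminal age")
    h = life_table.annual_hazard()
    n_ages = len(h)
    e = rng.exponential(size=len(ages))
    out = np.empty(len(ages))
    # walk the hazard years from each woman's current age until the
    # cumulative hazard exhausts her exponential draw
    for i, (a0, target) in enumerate(zip(ages, e)):
        year = int(np.floor(a0))
        pos = a0
        remaining = target
        while year < n_ages:
            width = year + 1.0 - pos
            hz = h[year]
            if np.isinf(hz):
                out[i] = float(year) if pos == year else pos
                break
            if hz * width >= remaining:
                out[i] = pos + (remaining / hz if hz > 0 else width)
                break
            remaining -= hz * width
            year += 1
            pos = float(year)
        else:
            out[i] = float(n_ages)
    out = np.minimum(out, life_table.terminal_age + 1.0)
    return float(out[0]) if scalar else out


def _sample_death_vectorized(ages: np.ndarray, life_table: LifeTable,
                             rng: np.random.Generator) -> np.ndarray:
    """Vectorized inverse-transform death sampling for whole cohorts."""
    h = life_table.annual_hazard()
    finite_h = np.where(np.isinf(h), 1e9, h)
    # cumulative hazard at integer ages
    cumH = np.concatenate([[0.0], np.cumsum(finite_h)])
    grid = np.arange(len(cumH), dtype=float)
    age0 = np.asarray(ages, dtype=float)
    year0 = np.floor(age0).astype(int)
    # hazard already accrued within the entry year
    H0 = cumH[year0] + finite_h[year0] * (age0 - year0)
    target = H0 + rng.exponential(size=len(age0))
    idx = np.searchsorted(cumH, target, side="right") - 1
    idx = np.clip(idx, 0, len(finite_h) - 1)
    frac = (target - cumH[idx]) / finite_h[idx]
    death = grid[idx] + np.minimum(frac, 1.0)
    death = np.maximum(death, age0 + 1e-9)
    return np.minimum(death, life_table.terminal_age + 1.0)


def init_population(n: int, fixtures: Fixtures, rng: np.random.Generator,
                    config: Config) -> Cohort:
    """The initial target population: n women aged 50-69 mid-screening.

    Screening rounds are anchored at ages 50, 52, ..., 68, so each woman's
    next invitation falls uniformly within the first two simulation years and
    the program's yearly screen volume is steady from the start. All initial
    women have been invited before; a configured ``naive_fraction`` is treated
    as new to the program (their first attended screen counts as initial).
    """
    pop = config.population
    if n < 0:
        raise ValueError("population size must be >= 0")
    age = rng.uniform(pop.initial_age_min, pop.initial_age_max, size=n)
    # next anchored round age strictly above the current age
    next_age = 50.0 + 2.0 * np.ceil((age - 50.0) / 2.0)
    next_age = np.where(next_age <= age, next_age + 2.0, next_age)
    death = _sample_death_vectorized(age, fixtures.life_table, rng)
    naive = rng.random(n) < pop.naive_fraction
    return Cohort(
        entry_time=np.zeros(n),
        entry_age=age,
        first_screen_time=next_age - age,
        first_screen_age=next_age,
        death_age_other=death,
        attended_before=~naive,
        is_entrant=np.zeros(n, dtype=bool),
    )


def entrant_population(fixtures: Fixtures, rng: np.random.Generator,
                       config: Config) -> Cohort:
    """Women entering through the biennial waves of the entry stream.

    Each wave enters at its wave time with ages 50 or 51 (equal probability)
    and is invited within the following 2-year cycle, uniformly spread.
    """
    es = fixtures.entry_stream
    n = es.total
    entry_time = np.repeat(es.times, es.sizes)
    ages = np.asarray(es.entry_ages, dtype=float)
    entry_age = ages[rng.integers(0, len(ages), size=n)]
    offset = rng.uniform(0.0, 2.0, size=n)
    death = _sample_death_vectorized(entry_age, fixtures.life_table, rng)
    return Cohort(
        entry_time=entry_time,
        entry_age=entry_age,
        first_screen_time=entry_time + offset,
        first_screen_age=entry_age + offset,
        death_age_other=death,
        attended_before=np.zeros(n, dtype=bool),
        is_entrant=np.ones(n, dtype=bool),
    )


def build_cohort(config: Config, fixtures: Fixtures,
                 rng: np.random.Generator) -> Cohort:
    init = init_population(config.population.scaled_initial_size, fixtures, rng, config)
    ent = entrant_population(fixtures, rng, config)
    return Cohort(*(np.concatenate([getattr(init, f), getattr(ent, f)])
                    for f in ("entry_time", "entry_age", "first_screen_time",
                              "first_screen_age", "death_age_other",
                              "attended_before", "is_entrant")))


def exit_rule(age: float, diagnosed: bool, exit_age: float = 70.0) -> str:
    """Whether a woman still generates screening events.

    Women reaching the upper age limit without a breast-cancer diagnosis stop
    generating screening events and cost accrual; diagnosed women (including
    interval cancers from the last round) remain followed to the horizon end.
    """
    if age >= exit_age and not diagnosed:
        return "remove"
    return "keep"
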