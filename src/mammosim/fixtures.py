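"""Synthetic demographic and epidemiologic inputs.

The simulator needs a female all-cause life table, an age-specific hazard of
pre-clinical breast-cancer onset, and the stream of 50-51-year-old entrants.
National statistics provide these in real applications; this module generates
statistically structured stand-ins (Gompertz-Makeham mortality, an
exponentially age-increasing onset hazard calibrated to the program's
screen-detection rate, equal biennial entry waves) and reads/writes them as
CSV so real tables can be substituted in the same format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config, ConfigError, IncidenceConfig, LifeTableConfig


@dataclass
class LifeTable:
    """Annual all-cause death probabilities q(x) for ages 0..terminal_age.

    q equals 1 at the terminal age, so the survival curve reaches 0.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)
        if self.ages.shape != self.qx.shape:
            raise ValueError("ages and qx must have the same length")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValueError("death probabilities must lie in [0,1]")
        if self.qx[-1] != 1.0:
            raise ValueError("terminal-age death probability must be 1")

    @property
    def terminal_age(self) -> int:
        return int(self.ages[-1])

    def annual_hazard(self) -> np.ndarray:
        """Piecewise-constant hazard h(x) = -log(1 - q(x)); inf at q=1."""
        with np.errstate(divide="ignore"):
            return -np.log1p(-self.qx)

    def survival_from(self, age: float) -> tuple[np.ndarray, np.ndarray]:
        """Conditional survival S(t | alive at `age`) on the age-year grid."""
        first = int(np.floor(age))
        edges = np.arange(first, self.terminal_age + 1, dtype=float)
        edges[0] = age
        exposure = np.diff(edges)
        h = self.annual_hazard()[first:first + len(exposure)]
        cum = np.concatenate([[0.0], np.cumsum(h * exposure)])
        return edges - age, np.exp(-cum)

    def life_expectancy(self, age: float) -> float:
        """Remaining life expectancy at `age` by numeric integration of S."""
        t, s = self.survival_from(age)
        return float(np.trapezoid(s, t))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())


def make_life_table(params: LifeTableConfig | None = None) -> LifeTable:
    """Gompertz-Makeham female life table stand-in.

    hazard(x) = makeham + a*exp(b*x); defaults are calibrated so the remaining
    life expectancy at age 50 is ~35 years (modern Spanish women).
    """
    p = params or LifeTableConfig()
    p.validate()
    ages = np.arange(0, p.terminal_age + 1)
    hazard = p.makeham + p.gompertz_a * np.exp(p.gompertz_b * ages)
    qx = 1.0 - np.exp(-hazard)
    qx[-1] = 1.0
    return LifeTable(ages, qx)


@dataclass
class IncidenceModel:
    """Annual hazard of pre-clinical breast-cancer onset by age.

    Hazard is zero below ``min_age``, constant beyond the last tabulated age.
    """

    ages: np.ndarray
    hazard: np.ndarray
    min_age: float = 30.0

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.hazard = np.asarray(self.hazard, dtype=float)
        if np.any(self.hazard < 0):
            raise ValueError("onset hazards must be >= 0")

    def hazard_at(self, age) -> np.ndarray:
        a = np.asarray(age, dtype=float)
        h = np.interp(a, self.ages, self.hazard,
                      left=self.hazard[0], right=self.hazard[-1])
        return np.where(a < self.min_age, 0.0, h)

    def scaled(self, multiplier: float) -> "IncidenceModel":
        if multiplier < 0:
            raise ValueError("multiplier must be >= 0")
        return IncidenceModel(self.ages.copy(), self.hazard * multiplier, self.min_age)

    def cumulative_hazard(self, age0: float, age_grid: np.ndarray) -> np.ndarray:
        """Integral of the hazard from age0 to each age in age_grid."""
        grid = np.asarray(age_grid, dtype=float)
        fine = np.linspace(age0, grid[-1], max(2, int((grid[-1] - age0) * 8) + 1))
        h = self.hazard_at(fine)
        cum_fine = np.concatenate([[0.0], np.cumsum((h[1:] + h[:-1]) / 2 * np.diff(fine))])
        return np.interp(grid, fine, cum_fine)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "hazard": self.hazard})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, min_age: float = 30.0) -> "IncidenceModel":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["hazard"].to_numpy(), min_age)


def base_incidence_model(params: IncidenceConfig | None = None) -> IncidenceModel:
    """Age-increasing onset hazard stand-in (before calibration).

    hazard(a) = multiplier * base_rate * exp(log_slope * (a - 50)) on
    [min_age, max_age], zero below min_age.
    """
    p = params or IncidenceConfig()
    p.validate()
    ages = np.arange(20.0, p.max_age + 1.0)
    hazard = p.multiplier * p.base_rate * np.exp(p.log_slope * (ages - 50.0))
    hazard[ages < p.min_age] = 0.0
    return IncidenceModel(ages, hazard, p.min_age)


@dataclass
class EntryStream:
    """Biennial waves of 50-51-year-old entrants."""

    times: np.ndarray
    sizes: np.ndarray
    entry_ages: tuple = (50, 51)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if np.any(self.sizes < 0):
            raise ValueError("wave sizes must be >= 0")
        if self.times.shape != self.sizes.shape:
            raise ValueError("times and sizes must align")

    @property
    def total(self) -> int:
        return int(self.sizes.sum())


def make_entry_stream(total_entrants: int, horizon_years: int = 20) -> EntryStream:
    """Split the configured entrant total into 10 equal biennial waves.

    Waves are placed at the close of each 2-year screening cycle (simulation
    times 2, 4, ..., 20): the cohort turning 50-51 during a cycle joins the
    target population when the cycle ends. Any remainder after equal division
    is spread one-per-wave over the earliest waves, so the stream conserves
    the configured total exactly.
    """
    if total_entrants < 0:
        raise ValueError("total_entrants must be >= 0")
    if horizon_years <= 0:
        raise ValueError("horizon_years must be > 0")
    n_waves = horizon_years // 2
    times = 2.0 * np.arange(1, n_waves + 1)
    base, rem = divmod(int(total_entrants), n_waves)
    sizes = np.full(n_waves, base, dtype=int)
    sizes[:rem] += 1
    return EntryStream(times, sizes)


@dataclass
class Fixtures:
    """The bundle of synthetic inputs one simulation run consumes."""

    life_table: LifeTable
    incidence: IncidenceModel
    entry_stream: EntryStream

    @classmethod
    def from_config(cls, config: Config) -> "Fixtures":
        pop = config.population
        return cls(
            life_table=make_life_table(config.natural_history.life_table),
            incidence=base_incidence_model(config.natural_history.incidence),
            entry_stream=make_entry_stream(pop.scaled_total_entrants, pop.horizon_years),
        )


class CalibrationError(RuntimeError):
    pass


def pilot_detection_rate(config: Config, multiplier: float, seed: int,
                         scale: float = 0.2) -> float:
    """Screen-detection rate (per screen) of one reduced-scale pilot run.

    Runs with the incidence hazard scaled by ``multiplier``, parameters at the
    PSA distribution means, and a fixed seed so the rate is a deterministic,
    non-decreasing function of the multiplier (common random numbers).
    """
    import copy

    from .budget import run_replication  # local import: engine depends on fixtures

    cfg = copy.deepcopy(config)
    cfg.population.scale = scale
    fx = Fixtures.from_config(cfg)
    fx.incidence = fx.incidence.scaled(multiplier)
    res = run_replication(cfg, seed, fixtures=fx, psa_mode="mean")
    arm = res.arms["screen_film"]
    if arm.counters["screens"] == 0:
        return 0.0
    return arm.counters["cancers_screen_detected"] / arm.counters["screens"]


def make_incidence_model(target_detection_rate: float, config: Config,
                         seed: int = 12345, tol: float = 5e-4,
                         max_iter: int = 20, pilot_scale: float = 0.2) -> IncidenceModel:
    """Calibrate the onset hazard to the program's screen-detection rate.

    Bisects a global multiplier of the base hazard curve until the pilot
    simulation's screen-detection rate is within ``tol`` (0.05 percentage
    points by default) of the target. Pilot runs share a seed, which makes the
    detection rate monotone in the multiplier and the bisection reproducible.
    """
    if not 0.0 < target_detection_rate < 0.05:
        raise ConfigError("target detection rate must be in (0, 0.05)")
    base = base_incidence_model(config.natural_history.incidence)

    lo, hi = 0.0, 1.0
    rate_hi = pilot_detection_rate(config, hi, seed, pilot_scale)
    grow = 0
    while rate_hi < target_detection_rate and grow < 8:
        lo, hi = hi, hi * 2.0
        rate_hi = pilot_detection_rate(config, hi, seed, pilot_scale)
        grow += 1
    if rate_hi < target_detection_rate:
        raise CalibrationError(
            f"cannot bracket target {target_detection_rate}: rate {rate_hi} at multiplier {hi}")

    mult = hi
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        rate = pilot_detection_rate(config, mid, seed, pilot_scale)
        if abs(rate - target_detection_rate) <= tol:
            return base.scaled(mid)
        if rate < target_detection_rate:
            lo = mid
        else:
            hi = mid
        mult = mid
    rate = pilot_detection_rate(config, mult, seed, pilot_scale)
    if abs(rate - target_detection_rate) <= tol:
        return base.scaled(mult)
    raise CalibrationError(
        f"calibration did not converge after {max_iter} iterations; "
        f"last bracket [{lo}, {hi}], rate {rate} vs target {target_detection_rate}")
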