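"""Model configuration: shipped defaults, YAML loading and validation.

Every number a practitioner might want to replace (participation and test
characteristics of the two mammography techniques, stage distributions,
unit costs, treatment phase table, natural-history stand-in parameters)
lives here, so a single YAML file fully determines a simulation experiment.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

TECHNIQUES = ("digital", "screen_film")
ROUND_TYPES = ("initial", "successive")
STAGES = ("CIS", "I", "II", "III", "IV")
WORKUP_TESTS = ("additional_mammogram", "ultrasound", "fnac", "core_biopsy", "open_biopsy")


class ConfigError(ValueError):
    """Raised when a configuration value violates the model's contracts."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class PopulationConfig:
    initial_size: int = 100_000
    total_entrants: int = 151_960
    horizon_years: int = 20
    start_year: int = 2010
    #: lower/upper bound of the initial population's age distribution (uniform)
    initial_age_min: float = 50.0
    initial_age_max: float = 70.0
    #: entrants are aged 50 or 51 with equal probability
    entry_ages: tuple[int, int] = (50, 51)
    exit_age: float = 70.0
    max_rounds: int = 10
    #: fraction of the initial population never invited before simulation start
    #: (calibrated so ~15.3% of screens are initial rounds at steady state)
    naive_fraction: float = 0.064
    #: global scale factor applied to initial_size and total_entrants
    scale: float = 1.0

    def validate(self) -> None:
        _check(self.initial_size >= 0, "population.initial_size must be >= 0")
        _check(self.total_entrants >= 0, "population.total_entrants must be >= 0")
        _check(self.horizon_years > 0, "population.horizon_years must be > 0")
        _check(0.0 <= self.naive_fraction <= 1.0, "population.naive_fraction must be in [0,1]")
        _check(self.scale > 0, "population.scale must be > 0")
        _check(self.initial_age_min < self.initial_age_max <= self.exit_age,
               "population ages must satisfy initial_age_min < initial_age_max <= exit_age")

    @property
    def scaled_initial_size(self) -> int:
        return int(round(self.initial_size * self.scale))

    @property
    def scaled_total_entrants(self) -> int:
        return int(round(self.total_entrants * self.scale))


@dataclass
class ParticipationConfig:
    p_initial: float = 0.787
    p_successive: float = 0.832
    #: Beta pseudo-count for the probabilistic sensitivity analysis
    kappa: float = 500.0
    #: "sticky": one Bernoulli(p_initial) gate at the first invitation decides
    #: ever-participation; participants attend later rounds w.p. p_successive.
    #: "independent": every invitation is an independent Bernoulli.
    model: str = "sticky"

    def validate(self) -> None:
        _check(0.0 <= self.p_initial <= 1.0, "participation.p_initial must be in [0,1]")
        _check(0.0 <= self.p_successive <= 1.0, "participation.p_successive must be in [0,1]")
        _check(self.kappa > 2.0, "participation.kappa must be > 2")
        _check(self.model in ("sticky", "independent"),
               f"participation.model must be 'sticky' or 'independent', got {self.model!r}")


@dataclass
class ScreeningConfig:
    sensitivity_mode: float = 0.8666
    sensitivity_kappa: float = 200.0
    #: specificity modes by technique and round type
    specificity: dict = field(default_factory=lambda: {
        "digital": {"initial": 0.888, "successive": 0.958},
        "screen_film": {"initial": 0.883, "successive": 0.954},
    })
    specificity_kappa: float = 500.0
    #: a clinical detection within this many years after the last negative
    #: screen is classified as an interval cancer
    interval_window_years: float = 2.0

    def validate(self) -> None:
        _check(0.0 < self.sensitivity_mode < 1.0, "screening.sensitivity_mode must be in (0,1)")
        _check(self.sensitivity_kappa > 2.0, "screening.sensitivity_kappa must be > 2")
        _check(self.specificity_kappa > 2.0, "screening.specificity_kappa must be > 2")
        for t in TECHNIQUES:
            _check(t in self.specificity, f"screening.specificity missing technique {t!r}")
            for r in ROUND_TYPES:
                v = self.specificity[t].get(r)
                _check(v is not None and 0.0 < v < 1.0,
                       f"screening.specificity[{t}][{r}] must be in (0,1)")


@dataclass
class StageConfig:
    #: screen-detected stage proportions per technique (CIS, I, II, III, IV);
    #: realized program distributions, used for both round types
    screen: dict = field(default_factory=lambda: {
        "digital": [0.214, 0.413, 0.294, 0.074, 0.004],
        "screen_film": [0.179, 0.441, 0.261, 0.117, 0.003],
    })
    #: clinically detected cancers (interval cancers and nonparticipants);
    #: identical for both techniques. Synthetic stand-in: a more advanced mix.
    clinical: list = field(default_factory=lambda: [0.08, 0.30, 0.35, 0.21, 0.06])
    #: Dirichlet total pseudo-count for the probabilistic sensitivity analysis
    dirichlet_concentration: float = 100.0

    def validate(self) -> None:
        for t in TECHNIQUES:
            v = self.screen.get(t)
            _check(v is not None and len(v) == 5 and all(x > 0 for x in v),
                   f"stages.screen[{t}] must be 5 positive proportions")
        _check(len(self.clinical) == 5 and all(x > 0 for x in self.clinical),
               "stages.clinical must be 5 positive proportions")
        _check(self.dirichlet_concentration > 0, "stages.dirichlet_concentration must be > 0")


@dataclass
class LifeTableConfig:
    """Gompertz-Makeham female all-cause mortality stand-in.

    hazard(age) = makeham + gompertz_a * exp(gompertz_b * age); defaults give a
    remaining life expectancy at age 50 of about 35 years.
    """
    makeham: float = 5e-4
    gompertz_a: float = 1.25e-5
    gompertz_b: float = 0.10
    terminal_age: int = 110

    def validate(self) -> None:
        _check(self.gompertz_a > 0 and self.gompertz_b > 0,
               "life_table Gompertz parameters must be positive")
        _check(self.makeham >= 0, "life_table.makeham must be >= 0")
        _check(self.terminal_age > 70, "life_table.terminal_age must exceed 70")


@dataclass
class IncidenceConfig:
    """Pre-clinical onset hazard stand-in: multiplier * base * exp(slope*(age-50)).

    The multiplier is calibrated so the simulated screen-detection rate matches
    the program's printed 0.643% per screen (see fixtures.make_incidence_model);
    the shipped default is the frozen result of that calibration.
    """
    base_rate: float = 0.003
    log_slope: float = 0.02
    min_age: float = 30.0
    max_age: float = 85.0
    multiplier: float = 0.993

    def validate(self) -> None:
        _check(self.base_rate > 0, "incidence.base_rate must be > 0")
        _check(self.multiplier >= 0, "incidence.multiplier must be >= 0")
        _check(20.0 <= self.min_age < self.max_age, "incidence ages must satisfy 20 <= min < max")


@dataclass
class NaturalHistoryConfig:
    #: sojourn (pre-clinical detectable phase) anchors: 2 y at age 40, 4 y at 50+
    sojourn_age_young: float = 40.0
    sojourn_years_young: float = 2.0
    sojourn_age_old: float = 50.0
    sojourn_years_old: float = 4.0
    #: exponential breast-cancer survival medians (years) by stage at detection,
    #: calibrated so cumulative 20-year BC mortality is ~0.75-0.77% of invited
    #: women with carcinoma in situ contributing ~1% of those deaths
    survival_median_years: dict = field(default_factory=lambda: {
        "CIS": 300.0, "I": 25.0, "II": 12.0, "III": 6.0, "IV": 3.0,
    })
    life_table: LifeTableConfig = field(default_factory=LifeTableConfig)
    incidence: IncidenceConfig = field(default_factory=IncidenceConfig)

    def validate(self) -> None:
        _check(self.sojourn_years_young > 0 and self.sojourn_years_old > 0,
               "sojourn durations must be > 0")
        _check(self.sojourn_age_young < self.sojourn_age_old,
               "sojourn age anchors must be increasing")
        for s in STAGES:
            _check(self.survival_median_years.get(s, 0) > 0,
                   f"survival_median_years[{s}] must be > 0")
        self.life_table.validate()
        self.incidence.validate()


@dataclass
class TreatmentPhaseRow:
    initial_months: float
    initial_cost_month: float
    followup_months: float
    followup_cost_month: float
    recurrence_prob: float


@dataclass
class CostConfig:
    #: cost per woman screened (EUR, 2009), also used for diagnostic mammograms
    screen_cost: dict = field(default_factory=lambda: {
        "digital": 42.28, "screen_film": 39.29,
    })
    workup_unit_costs: dict = field(default_factory=lambda: {
        "ultrasound": 16.69,
        "fnac": 303.25,
        "core_biopsy": 270.16,
        "open_biopsy": 1388.0,
    })
    #: cumulative consumer price index from 2005 to 2009
    cpi_rate: float = 0.079
    #: treatment-phase table prices are 2005 values and must be CPI-adjusted;
    #: set False if the table is already expressed in 2009 EUR
    treatment_costs_are_2005: bool = True
    #: per-stage monthly treatment phases; follow-up = 120 - (initial - 1) months
    treatment: dict = field(default_factory=lambda: {
        "CIS": {"initial_months": 5.75, "initial_cost_month": 2006.25,
                "followup_months": 115.25, "followup_cost_month": 132.10,
                "recurrence_prob": 0.0275},
        "I": {"initial_months": 9.40, "initial_cost_month": 2006.25,
              "followup_months": 111.60, "followup_cost_month": 291.87,
              "recurrence_prob": 0.0785},
        "II": {"initial_months": 10.62, "initial_cost_month": 2236.92,
               "followup_months": 110.38, "followup_cost_month": 577.35,
               "recurrence_prob": 0.1468},
        "III": {"initial_months": 11.11, "initial_cost_month": 2236.92,
                "followup_months": 109.89, "followup_cost_month": 737.65,
                "recurrence_prob": 0.3538},
    })
    advanced_cost_month: float = 3438.71

    def validate(self) -> None:
        for t in TECHNIQUES:
            _check(self.screen_cost.get(t, 0) > 0, f"costs.screen_cost[{t}] must be > 0")
        for k, v in self.workup_unit_costs.items():
            _check(v > 0, f"costs.workup_unit_costs[{k}] must be > 0")
        _check(self.cpi_rate >= 0, "costs.cpi_rate must be >= 0")
        _check(self.advanced_cost_month > 0, "costs.advanced_cost_month must be > 0")
        for s in ("CIS", "I", "II", "III"):
            row = self.treatment.get(s)
            _check(row is not None, f"costs.treatment missing stage {s}")
            _check(row["initial_months"] > 0 and row["followup_months"] > 0,
                   f"costs.treatment[{s}] durations must be > 0")
            _check(0.0 <= row["recurrence_prob"] <= 1.0,
                   f"costs.treatment[{s}].recurrence_prob must be in [0,1]")
            # Table note: follow-up runs from surgery to 10 years, i.e.
            # 120 months minus the initial phase except its first month.
            expected = 120.0 - (row["initial_months"] - 1.0)
            _check(math.isclose(row["followup_months"], expected, abs_tol=0.01),
                   f"costs.treatment[{s}]: follow-up must equal 120-(initial-1) months")

    def phase_row(self, stage: str) -> TreatmentPhaseRow:
        r = self.treatment[stage]
        return TreatmentPhaseRow(r["initial_months"], r["initial_cost_month"],
                                 r["followup_months"], r["followup_cost_month"],
                                 r["recurrence_prob"])


@dataclass
class WorkupConfig:
    """Per-technique additional-test margins, as program counts.

    ``counts[technique][test] / recalls[technique]`` is the probability that a
    recalled woman receives that test; the same margins are used for initial
    and successive rounds (per-round margins are not published).
    """
    recalls: dict = field(default_factory=lambda: {
        "digital": 44_536, "screen_film": 47_931,
    })
    counts: dict = field(default_factory=lambda: {
        "digital": {"additional_mammogram": 19_085, "ultrasound": 34_241,
                    "fnac": 11_812, "core_biopsy": 2_725, "open_biopsy": 302},
        "screen_film": {"additional_mammogram": 28_529, "ultrasound": 37_809,
                        "fnac": 20_729, "core_biopsy": 4_611, "open_biopsy": 1_544},
    })

    def margins(self, technique: str) -> dict:
        total = self.recalls[technique]
        return {t: self.counts[technique][t] / total for t in WORKUP_TESTS}

    def validate(self) -> None:
        for t in TECHNIQUES:
            _check(self.recalls.get(t, 0) > 0, f"workup.recalls[{t}] must be > 0")
            m = self.margins(t)
            for test, p in m.items():
                _check(0.0 <= p <= 1.0, f"workup margin {t}/{test} outside [0,1]")
            invasive = m["fnac"] + m["core_biopsy"] + m["open_biopsy"]
            _check(m["ultrasound"] >= invasive,
                   f"workup margins for {t}: ultrasound margin must cover invasive tests")


@dataclass
class Config:
    population: PopulationConfig = field(default_factory=PopulationConfig)
    participation: ParticipationConfig = field(default_factory=ParticipationConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    stages: StageConfig = field(default_factory=StageConfig)
    natural_history: NaturalHistoryConfig = field(default_factory=NaturalHistoryConfig)
    costs: CostConfig = field(default_factory=CostConfig)
    workup: WorkupConfig = field(default_factory=WorkupConfig)

    def validate(self) -> "Config":
        for f in dataclasses.fields(self):
            getattr(self, f.name).validate()
        return self

    def replace(self, **kwargs: Any) -> "Config":
        """Deep copy with top-level sections replaced."""
        new = copy.deepcopy(self)
        for k, v in kwargs.items():
            setattr(new, k, v)
        return new.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _update_dataclass(obj: Any, data: dict, path: str = "") -> None:
    valid = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(f"unknown config key {path + key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _update_dataclass(current, value, path=f"{path}{key}.")
        else:
            setattr(obj, key, value)


def default_config(scale: float = 1.0) -> Config:
    cfg = Config()
    cfg.population.scale = scale
    return cfg.validate()


def load_config(path: str | None = None, overrides: dict | None = None) -> Config:
    """Build a Config from the shipped defaults, a YAML file, and overrides.

    The YAML file mirrors the dataclass tree (sections ``population``,
    ``participation``, ``screening``, ``stages``, ``natural_history``,
    ``costs``, ``workup``); unknown keys raise ConfigError.
    """
    cfg = Config()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        _update_dataclass(cfg, data)
    if overrides:
        _update_dataclass(cfg, overrides)
    return cfg.validate()


def save_config(cfg: Config, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
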