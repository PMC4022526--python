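"""Replication orchestration, budget-impact aggregation and PSA scenarios.

A replication pairs two arms (digital vs screen-film) on one shared cohort
with common random numbers; the budget impact is the yearly cost difference
(screen-film minus digital, so positive values are savings from switching),
averaged over replications with normal-approximation confidence intervals.
Replications are classified into scenario groups by their realized detection
and recall rate differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Config, STAGES, TECHNIQUES
from .engine import ArmResult, simulate_replication
from .fixtures import Fixtures
from .psa import sample_parameter_draw

CATEGORIES = ("overall", "screening", "additional_tests", "treatment")

DM_BETTER = "DM_better"
SFM_BETTER = "SFM_better"
INTERMEDIATE = "intermediate"


@dataclass
class RunResult:
    """Paired-arm outcome of one replication."""

    replication: int
    seed: int
    arms: dict  # technique -> ArmResult

    def cost_matrix(self, technique: str) -> np.ndarray:
        """(years, 4) matrix: overall, screening, additional tests, treatment."""
        cs = self.arms[technique].cost_stream
        return np.column_stack([cs.overall, cs.screening, cs.additional_tests, cs.treatment])

    def difference_matrix(self) -> np.ndarray:
        """Yearly screen-film minus digital costs (positive = saving)."""
        return self.cost_matrix("screen_film") - self.cost_matrix("digital")

    @property
    def years(self) -> np.ndarray:
        return self.arms["digital"].cost_stream.years

    def scenario_inputs(self) -> tuple[float, float, float, float]:
        dm, sfm = self.arms["digital"].rates, self.arms["screen_film"].rates
        return (dm["detection_rate_per_1000"], sfm["detection_rate_per_1000"],
                dm["recall_rate_pct"], sfm["recall_rate_pct"])


def replication_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Counter-based per-replication seed derivation (order-independent)."""
    return [np.random.SeedSequence(entropy=master_seed, spawn_key=(i,)) for i in range(n)]


def run_replication(config: Config, seed, replication: int = 0,
                    fixtures: Fixtures | None = None,
                    psa_mode: str = "sample") -> RunResult:
    """Run one paired replication from a seed.

    One ParameterDraw is sampled, one cohort is built with shared natural
    histories and participation, and both arms execute on common random
    numbers; the result is fully determined by (config, fixtures, seed).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    fx = fixtures if fixtures is not None else Fixtures.from_config(config)
    try:
        draw = sample_parameter_draw(config, rng, psa_mode=psa_mode)
        arms = simulate_replication(config, fx, draw, rng)
    except Exception as exc:
        raise RuntimeError(f"replication {replication} failed: {exc}") from exc
    seed_int = ss.entropy if isinstance(ss.entropy, int) else 0
    return RunResult(replication=replication, seed=seed_int, arms=arms)


def run_replications(config: Config, n_replications: int, master_seed: int,
                     fixtures: Fixtures | None = None,
                     psa_mode: str = "sample") -> list[RunResult]:
    fx = fixtures if fixtures is not None else Fixtures.from_config(config)
    out = []
    for i, ss in enumerate(replication_seeds(master_seed, n_replications)):
        out.append(run_replication(config, ss, replication=i, fixtures=fx,
                                   psa_mode=psa_mode))
    return out


@dataclass
class BudgetImpact:
    """Across-replication yearly cost differences with 95% CIs."""

    years: np.ndarray
    n_replications: int
    mean: dict    # category -> yearly means of (screen-film - digital)
    ci_low: dict
    ci_high: dict
    mean_costs: dict  # technique -> category -> yearly mean costs

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, year in enumerate(self.years):
            row = {"year": int(year)}
            for cat in CATEGORIES:
                row[f"diff_{cat}"] = self.mean[cat][j]
                row[f"diff_{cat}_ci_low"] = self.ci_low[cat][j]
                row[f"diff_{cat}_ci_high"] = self.ci_high[cat][j]
                for t in TECHNIQUES:
                    row[f"{t}_{cat}"] = self.mean_costs[t][cat][j]
            rows.append(row)
        return pd.DataFrame(rows)

    def saving_pct_of_screen_film(self, year_index: int) -> float:
        """Overall saving as % of the screen-film overall cost in that year."""
        sf = self.mean_costs["screen_film"]["overall"][year_index]
        return 100.0 * self.mean["overall"][year_index] / sf if sf else 0.0


def aggregate(results: list[RunResult]) -> BudgetImpact:
    """Mean yearly differences and 95% normal-approximation CIs.

    CI = mean +- 1.96 * SD/sqrt(n) across replications; the decomposition
    (overall = screening + additional + treatment) holds exactly per
    replication and therefore in the means.
    """
    if len(results) < 2:
        raise ValueError("aggregation requires at least 2 replications")
    diffs = np.stack([r.difference_matrix() for r in results])  # (R, Y, 4)
    years = results[0].years
    n = len(results)
    mean = diffs.mean(axis=0)
    se = diffs.std(axis=0, ddof=1) / np.sqrt(n)
    lo, hi = mean - 1.96 * se, mean + 1.96 * se
    mean_costs = {}
    for t in TECHNIQUES:
        costs = np.stack([r.cost_matrix(t) for r in results]).mean(axis=0)
        mean_costs[t] = {cat: costs[:, i] for i, cat in enumerate(CATEGORIES)}
    return BudgetImpact(
        years=years, n_replications=n,
        mean={cat: mean[:, i] for i, cat in enumerate(CATEGORIES)},
        ci_low={cat: lo[:, i] for i, cat in enumerate(CATEGORIES)},
        ci_high={cat: hi[:, i] for i, cat in enumerate(CATEGORIES)},
        mean_costs=mean_costs,
    )


def classify_run(detection_dm: float, detection_sfm: float,
                 recall_dm: float, recall_sfm: float,
                 threshold_detection: float = 0.5,
                 threshold_recall: float = 0.5) -> str:
    """Scenario group from realized rates (detection per 1000, recall %).

    A detection rate at least 0.5 per 1000 higher is "better"; a recall rate
    at least 0.5 percentage points lower is "better"; boundary values count
    as better. A technique's group requires both rates better, or one better
    and the other similar; opposite-direction splits and both-similar runs
    are the intermediate scenario.
    """
    for v in (detection_dm, detection_sfm, recall_dm, recall_sfm):
        if v < 0:
            raise ValueError("rates must be >= 0")
    d = detection_dm - detection_sfm        # positive: DM detects more
    r = recall_sfm - recall_dm              # positive: DM recalls less
    det_dm, det_sfm = d >= threshold_detection, -d >= threshold_detection
    rec_dm, rec_sfm = r >= threshold_recall, -r >= threshold_recall
    det_similar = not (det_dm or det_sfm)
    rec_similar = not (rec_dm or rec_sfm)
    if (det_dm and rec_dm) or (det_dm and rec_similar) or (rec_dm and det_similar):
        return DM_BETTER
    if (det_sfm and rec_sfm) or (det_sfm and rec_similar) or (rec_sfm and det_similar):
        return SFM_BETTER
    return INTERMEDIATE


def classify_results(results: list[RunResult]) -> list[str]:
    return [classify_run(*r.scenario_inputs()) for r in results]


def summarize_by_group(results: list[RunResult]) -> dict:
    """Scenario-group counts and per-group budget impacts.

    Groups with fewer than 2 replications are reported with their count and
    no aggregated impact (CIs undefined).
    """
    labels = classify_results(results)
    out = {}
    for group in (DM_BETTER, SFM_BETTER, INTERMEDIATE):
        members = [r for r, lab in zip(results, labels) if lab == group]
        impact = aggregate(members) if len(members) >= 2 else None
        out[group] = {"n": len(members), "impact": impact}
    return out


# ---------------------------------------------------------------------------
# report tables


def table2(result: RunResult) -> pd.DataFrame:
    """Cumulative health and validation outcomes per arm (Table-2 layout)."""
    rows = []
    for t in TECHNIQUES:
        c = result.arms[t].counters
        r = result.arms[t].rates
        all_cancers = c["cancers_screen_detected"] + c["interval_cancers"] \
            + c["clinical_nonscreening"]
        row = {
            "technique": t,
            "invited_women": c["invited_women"],
            "screens": c["screens"],
            "screens_initial": c["screens_initial"],
            "screens_successive": c["screens_successive"],
            "initial_share_pct": r["initial_share_pct"],
            "recalls": c["recalls"],
            "recall_rate_pct": r["recall_rate_pct"],
            "false_positives": c["fp"],
            "fp_rate_pct": r["fp_rate_pct"],
            "fp_rate_initial_pct": r["fp_rate_initial_pct"],
            "fp_rate_successive_pct": r["fp_rate_successive_pct"],
            "cancers_screen_detected": c["cancers_screen_detected"],
            "detection_rate_pct": r["detection_rate_pct"],
            "interval_cancers": c["interval_cancers"],
            "interval_false_negative": c["interval_false_negative"],
            "interval_true": c["interval_true"],
            "interval_pct_of_screen_detected": (
                100.0 * c["interval_cancers"] / c["cancers_screen_detected"]
                if c["cancers_screen_detected"] else 0.0),
            "interval_pct_of_all_cancers": (
                100.0 * c["interval_cancers"] / all_cancers if all_cancers else 0.0),
            "cancers_clinical": c["cancers_clinical"],
            "bc_deaths": c["bc_deaths"],
            "bc_mortality_pct_of_invited": 100.0 * c["bc_deaths"] / c["invited_women"],
        }
        for s in STAGES:
            row[f"screen_detected_{s}"] = c["cancers_screen_by_stage"][s]
            row[f"bc_deaths_{s}"] = c["bc_deaths_by_stage"][s]
        rows.append(row)
    return pd.DataFrame(rows)


def table3(impact: BudgetImpact) -> pd.DataFrame:
    """Yearly costs per arm and differences with CIs (Table-3 layout)."""
    return impact.to_frame()


def groups_table(results: list[RunResult]) -> pd.DataFrame:
    summary = summarize_by_group(results)
    rows = []
    for group, info in summary.items():
        row = {"group": group, "n_runs": info["n"]}
        if info["impact"] is not None:
            imp = info["impact"]
            last = len(imp.years) - 1
            for j, label in ((9, "year10"), (last, "year20")):
                row[f"diff_overall_{label}"] = imp.mean["overall"][j]
                row[f"diff_overall_{label}_ci_low"] = imp.ci_low["overall"][j]
                row[f"diff_overall_{label}_ci_high"] = imp.ci_high["overall"][j]
        rows.append(row)
    return pd.DataFrame(rows)
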