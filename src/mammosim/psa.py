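"""Probabilistic sensitivity analysis: parameter distributions and draws.

Each replication of the paired-arm simulation runs with one ``ParameterDraw``:
sensitivity and specificity of each mammography technique, participation
probabilities, stage-at-detection distributions and work-up test combination
distributions. Uncertain probabilities are sampled from mode-parameterized
Beta distributions, stage vectors from Dirichlet distributions; the same
draw is used by both arms of a replication except where parameters are
technique-specific by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import Config, ROUND_TYPES, STAGES, TECHNIQUES
from .screening import decompose_workup_margins

__all__ = [
    "BetaSpec", "DirichletSpec", "TechniqueScreeningParams", "ParticipationParams",
    "ParameterDraw", "beta_shapes_from_mode", "sample_parameter_draw",
    "dirichlet_stage_sample",
]


def beta_shapes_from_mode(mode: float, concentration: float) -> tuple[float, float]:
    """Shape pair (alpha, beta) of the Beta distribution with the given mode.

    The concentration kappa = alpha + beta is the total pseudo-count; the
    density's mode is (alpha-1)/(kappa-2), so ``alpha = mode*(kappa-2)+1``.
    Requires kappa > 2 for the mode to exist in the interior.
    """
    if not 0.0 < mode < 1.0:
        raise ValueError(f"mode must be in (0,1), got {mode}")
    if concentration <= 2.0:
        raise ValueError(f"concentration must exceed 2, got {concentration}")
    alpha = mode * (concentration - 2.0) + 1.0
    return alpha, concentration - alpha


@dataclass(frozen=True)
class BetaSpec:
    """Mode-parameterized Beta distribution for one probability parameter."""

    mode: float
    concentration: float

    def __post_init__(self) -> None:
        beta_shapes_from_mode(self.mode, self.concentration)  # validates

    @property
    def shapes(self) -> tuple[float, float]:
        return beta_shapes_from_mode(self.mode, self.concentration)

    @property
    def mean(self) -> float:
        a, b = self.shapes
        return a / (a + b)

    def sample(self, rng: np.random.Generator, size=None):
        a, b = self.shapes
        return rng.beta(a, b, size=size)


@dataclass(frozen=True)
class DirichletSpec:
    """Dirichlet distribution over the five detection stages (CIS, I-IV)."""

    alphas: tuple

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        if a.shape != (5,):
            raise ValueError(f"expected 5 stage alphas ({', '.join(STAGES)}), got {a.shape}")
        if not np.all(a > 0):
            raise ValueError("all Dirichlet alphas must be positive")
        object.__setattr__(self, "alphas", tuple(float(x) for x in a))

    @classmethod
    def from_proportions(cls, props, concentration: float) -> "DirichletSpec":
        p = np.asarray(props, dtype=float)
        p = p / p.sum()
        return cls(tuple(p * concentration))

    @property
    def mean(self) -> np.ndarray:
        a = np.asarray(self.alphas)
        return a / a.sum()

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.dirichlet(self.alphas)


def dirichlet_stage_sample(spec: DirichletSpec, rng: np.random.Generator) -> np.ndarray:
    """One stage probability vector: 5 nonnegative entries summing to 1."""
    return spec.sample(rng)


@dataclass
class TechniqueScreeningParams:
    sensitivity: float
    specificity_initial: float
    specificity_successive: float
    cost_per_screen: float

    def specificity(self, round_type: str) -> float:
        if round_type == "initial":
            return self.specificity_initial
        if round_type == "successive":
            return self.specificity_successive
        raise KeyError(f"unknown round type {round_type!r}")

    def validate(self) -> None:
        for name in ("sensitivity", "specificity_initial", "specificity_successive"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0,1], got {v}")
        if self.cost_per_screen <= 0:
            raise ValueError("cost_per_screen must be > 0")


@dataclass
class ParticipationParams:
    p_initial: float
    p_successive: float

    def validate(self) -> None:
        for name in ("p_initial", "p_successive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class ParameterDraw:
    """One replication's realized values of all probabilistic parameters.

    ``stage_dist`` maps (setting, round_type, technique) to a stage probability
    vector; the clinical-setting vector is shared between techniques and round
    types. ``workup_dist`` maps (technique, round_type) to a distribution over
    work-up test combinations as ``(combos, probabilities)``.
    """

    techniques: dict
    participation: ParticipationParams
    stage_dist: dict
    workup_dist: dict

    def validate(self) -> None:
        for t in TECHNIQUES:
            self.techniques[t].validate()
        self.participation.validate()
        for key, vec in self.stage_dist.items():
            v = np.asarray(vec)
            if not (np.all(v >= 0) and abs(v.sum() - 1.0) <= 1e-9):
                raise ValueError(f"stage distribution {key} does not normalize to 1")
        for key, (combos, probs) in self.workup_dist.items():
            p = np.asarray(probs)
            if not (len(combos) == len(p) and np.all(p >= 0) and abs(p.sum() - 1.0) <= 1e-9):
                raise ValueError(f"work-up distribution {key} does not normalize to 1")


def _beta_value(spec: BetaSpec, rng: np.random.Generator, psa_mode: str) -> float:
    if psa_mode == "sample":
        return float(spec.sample(rng))
    if psa_mode == "mean":
        return spec.mean
    if psa_mode == "mode":
        return spec.mode
    raise ValueError(f"unknown psa_mode {psa_mode!r}")


def _dirichlet_value(spec: DirichletSpec, rng: np.random.Generator, psa_mode: str) -> np.ndarray:
    if psa_mode == "sample":
        return spec.sample(rng)
    # mean and mode coincide for the comparisons we make at desk scale;
    # the Dirichlet mean alpha/sum(alpha) is the realized program distribution
    return spec.mean


def sample_parameter_draw(config: Config, rng: np.random.Generator,
                          psa_mode: str = "sample") -> ParameterDraw:
    """Sample one ParameterDraw from the configured PSA distributions.

    Sensitivity is sampled independently per technique from the SAME BetaSpec,
    so replications realize scenarios with similar or different sensitivities
    favoring either technique; specificities come from technique- and
    round-specific BetaSpecs, stage distributions from Dirichlets.

    ``psa_mode='mean'`` (or ``'mode'``) returns the degenerate draw at the
    distribution means (modes), used for single-replication validation runs.
    """
    scr, part, stg = config.screening, config.participation, config.stages
    sens_spec = BetaSpec(scr.sensitivity_mode, scr.sensitivity_kappa)

    techniques = {}
    for t in TECHNIQUES:  # fixed iteration order: digital, screen_film
        sens = _beta_value(sens_spec, rng, psa_mode)
        spec_init = _beta_value(
            BetaSpec(scr.specificity[t]["initial"], scr.specificity_kappa), rng, psa_mode)
        spec_succ = _beta_value(
            BetaSpec(scr.specificity[t]["successive"], scr.specificity_kappa), rng, psa_mode)
        techniques[t] = TechniqueScreeningParams(
            sensitivity=sens,
            specificity_initial=spec_init,
            specificity_successive=spec_succ,
            cost_per_screen=config.costs.screen_cost[t],
        )

    participation = ParticipationParams(
        p_initial=_beta_value(BetaSpec(part.p_initial, part.kappa), rng, psa_mode),
        p_successive=_beta_value(BetaSpec(part.p_successive, part.kappa), rng, psa_mode),
    )

    stage_dist = {}
    for t in TECHNIQUES:
        spec_d = DirichletSpec.from_proportions(stg.screen[t], stg.dirichlet_concentration)
        vec = _dirichlet_value(spec_d, rng, psa_mode)
        for r in ROUND_TYPES:
            stage_dist[("screen", r, t)] = vec
    clin_spec = DirichletSpec.from_proportions(stg.clinical, stg.dirichlet_concentration)
    clin_vec = _dirichlet_value(clin_spec, rng, psa_mode)
    for t in TECHNIQUES:
        for r in ROUND_TYPES:
            stage_dist[("clinical", r, t)] = clin_vec

    workup_dist = {}
    for t in TECHNIQUES:
        combos, probs = decompose_workup_margins(config.workup.margins(t))
        for r in ROUND_TYPES:
            workup_dist[(t, r)] = (combos, probs)

    draw = ParameterDraw(techniques=techniques, participation=participation,
                         stage_dist=stage_dist, workup_dist=workup_dist)
    draw.validate()
    return draw
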