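"""Screening-process primitives: participation, screen outcomes, work-up.

The vectorized engine (``mammosim.engine``) applies the same formulas to whole
cohorts; the scalar operations here define the contracts and serve as the unit
surface. The work-up combination decomposition lives here because its margins
are a screening-program quantity (tests per recalled woman).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import WORKUP_TESTS

__all__ = [
    "ScreenOutcome", "build_participation_profile", "perform_screen",
    "false_negative_followup", "decompose_workup_margins", "sample_workup",
]


@dataclass(frozen=True)
class ScreenOutcome:
    label: str  # TN | FP | TP | FN
    round_type: str
    technique: str
    time: float


def build_participation_profile(p_init: float, p_succ: float,
                                rng: np.random.Generator,
                                n_rounds: int = 10,
                                model: str = "sticky",
                                attended_before: bool = False) -> np.ndarray:
    """Attendance indicators for a woman's (at most 10) potential invitations.

    The profile is generated once per woman and shared by both arms, which is
    what makes the two arms of a replication identical except for technique
    parameters.

    Under the default ``sticky`` model a single Bernoulli(p_init) gate at the
    first invitation decides whether the woman ever participates; participants
    attend the first invitation and each later one independently with
    probability p_succ. Women already screened before simulation start
    (``attended_before``) have passed the gate historically and attend every
    in-horizon invitation with probability p_succ. Under ``independent`` every
    indicator is an independent Bernoulli (first p_init, later p_succ).
    """
    if n_rounds > 10:
        raise ValueError("a woman receives at most 10 screening invitations")
    u = rng.random(n_rounds)
    if model == "independent":
        probs = np.full(n_rounds, p_succ)
        if not attended_before and n_rounds > 0:
            probs[0] = p_init
        return u < probs
    if model != "sticky":
        raise ValueError(f"unknown participation model {model!r}")
    profile = u < p_succ
    if not attended_before and n_rounds > 0:
        gate = u[0] < p_init
        profile[0] = gate
        profile &= gate
    return profile


def perform_screen(in_preclinical: bool, sensitivity: float, specificity: float,
                   u: float) -> str:
    """Classify one attended screen as TP/FN (cancer present) or FP/TN (free).

    A single uniform drives the decision so that, under common random numbers,
    a higher specificity can only turn an FP into a TN and a higher sensitivity
    an FN into a TP.
    """
    if in_preclinical:
        return "TP" if u < sensitivity else "FN"
    return "FP" if u > specificity else "TN"


def false_negative_followup(clinical_onset_age: float, next_screen_age: float | None) -> str:
    """Resolve a false-negative: interval cancer vs rescreening.

    A missed cancer surfaces clinically at the woman's clinical onset age
    (interval cancer) unless a later attended screen happens first, in which
    case the screen result is drawn again. Returns which event comes first.
    """
    if next_screen_age is None or clinical_onset_age <= next_screen_age:
        return "interval"
    return "rescreen"


def decompose_workup_margins(margins: dict) -> tuple[list, np.ndarray]:
    """Build a distribution over work-up test combinations from per-test margins.

    ``margins[test]`` is the probability that a recalled woman receives the
    test. The decomposition is structural: every invasive test (FNAC, core
    biopsy, open surgical biopsy — treated as mutually exclusive) is
    accompanied by an ultrasound; the remaining ultrasound margin is
    ultrasound-without-invasive-test; women with neither get an additional
    mammogram (every recalled woman has at least one test); additional
    mammograms are then spread over the other groups so their margin is met
    exactly. All five margins are reproduced exactly by construction.
    """
    m = {t: float(margins[t]) for t in WORKUP_TESTS}
    for t, p in m.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"margin for {t} outside [0,1]: {p}")
    invasive = {t: m[t] for t in ("fnac", "core_biopsy", "open_biopsy")}
    p_inv = sum(invasive.values())
    if p_inv > 1.0:
        raise ValueError("invasive test margins exceed 1")
    if m["ultrasound"] < p_inv:
        raise ValueError("ultrasound margin must cover the invasive tests")
    p_us_only = m["ultrasound"] - p_inv
    p_none = 1.0 - p_inv - p_us_only  # forced additional mammogram
    if p_none < 0:
        raise ValueError("ultrasound margin exceeds 1")
    # additional mammograms: p_none are forced; the rest attach independently
    # to the ultrasound-bearing groups at rate a
    p_us_bearing = 1.0 - p_none
    if m["additional_mammogram"] < p_none - 1e-12:
        raise ValueError("additional-mammogram margin below the no-other-test mass")
    a = 0.0 if p_us_bearing == 0 else (m["additional_mammogram"] - p_none) / p_us_bearing
    if not -1e-12 <= a <= 1.0 + 1e-12:
        raise ValueError("additional-mammogram margin incompatible with other margins")
    a = min(max(a, 0.0), 1.0)

    combos: list[tuple] = []
    probs: list[float] = []

    def add(combo: tuple, p: float) -> None:
        if p > 1e-15:
            combos.append(combo)
            probs.append(p)

    add(("additional_mammogram",), p_none)
    add(("ultrasound",), p_us_only * (1.0 - a))
    add(("ultrasound", "additional_mammogram"), p_us_only * a)
    for t, p in invasive.items():
        add(("ultrasound", t), p * (1.0 - a))
        add(("ultrasound", t, "additional_mammogram"), p * a)

    arr = np.asarray(probs)
    arr = arr / arr.sum()
    return combos, arr


def workup_combo_margins(combos: list, probs: np.ndarray) -> dict:
    """Per-test margins implied by a combination distribution (for checking)."""
    out = {t: 0.0 for t in WORKUP_TESTS}
    for combo, p in zip(combos, probs):
        for t in combo:
            out[t] += float(p)
    return out


def sample_workup(technique: str, round_type: str, draw, rng_or_u) -> tuple:
    """Sample one work-up combination for a recalled (TP or FP) woman."""
    combos, probs = draw.workup_dist[(technique, round_type)]
    if len(combos) == 0:
        raise ValueError(f"empty work-up distribution for {(technique, round_type)}")
    u = rng_or_u.random() if isinstance(rng_or_u, np.random.Generator) else float(rng_or_u)
    idx = int(np.searchsorted(np.cumsum(probs), u, side="right"))
    idx = min(idx, len(combos) - 1)
    return combos[idx]
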