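"""Screening strategies and within-cycle screening/detection/treatment events.

Strategies differ only in how often endoscopic screening is offered
(never, once per lifetime, or every 2/3/5/10 years) inside the 40-69
eligibility window.  The per-cycle event operators act on an occupancy
vector over the state space and return the moved mass plus a tally of
countable events (true/false positives, complications, costs by
category).  All operators conserve total mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .state_space import LOW_GRADE_STAGES, StateSpace

#: allowed interval sentinels: "none", "once", or a positive year count
INTERVALS = ("none", "once", 2, 3, 5, 10)

#: default annual probability of a symptom-driven (self-initiated)
#: diagnostic examination, by severity tier
DEFAULT_SELF_EXAM = {"severe": 0.01, "early": 0.20, "advanced": 0.70}

_SELF_EXAM_TIER = {
    "severe_dysplasia_cis": "severe",
    "hgin_cis": "severe",
    "early_cancer": "early",
    "advanced_cancer": "advanced",
}


class StrategyError(ValueError):
    """Bad strategy or screening-parameter configuration."""


@dataclass(frozen=True)
class Strategy:
    """A screening schedule: frequency plus eligibility window."""

    name: str
    interval: int | str  # "none", "once", or years between rounds
    eligible_age_range: tuple[int, int] = (40, 69)

    def __post_init__(self) -> None:
        if self.interval not in INTERVALS:
            raise StrategyError(f"unknown screening interval "
                                f"{self.interval!r}; expected one of "
                                f"{INTERVALS}")
        lo, hi = self.eligible_age_range
        if lo > hi:
            raise StrategyError("eligibility bounds out of order")


#: the strategy menu compared in the analysis
STRATEGY_MENU: tuple[Strategy, ...] = (
    Strategy("no_screening", "none"),
    Strategy("once_per_lifetime", "once"),
    Strategy("every_10y", 10),
    Strategy("every_5y", 5),
    Strategy("every_3y", 3),
    Strategy("every_2y", 2),
)


def get_strategy(name: str) -> Strategy:
    for s in STRATEGY_MENU:
        if s.name == name:
            return s
    raise StrategyError(f"unknown strategy {name!r}")


def screening_cycles(strategy: Strategy, initial_mean_age: int,
                     horizon_cycles: int) -> set[int]:
    """Cycle indices at which a screening round is offered.

    Rounds start at cycle 0 and repeat every ``interval`` years while the
    cohort's mean age stays inside the eligibility window; "once" yields
    {0} and "none" yields the empty set.
    """
    if strategy.interval == "none":
        return set()
    if strategy.interval == "once":
        return {0} if initial_mean_age <= strategy.eligible_age_range[1] \
            else set()
    upper = strategy.eligible_age_range[1]
    k = int(strategy.interval)
    return {t for t in range(0, horizon_cycles, k)
            if initial_mean_age + t <= upper}


def distinct_strategies(initial_mean_age: int, horizon_cycles: int,
                        menu: tuple[Strategy, ...] = STRATEGY_MENU
                        ) -> list[Strategy]:
    """Menu trimmed to strategies with distinct screening schedules.

    At older initial ages several intervals collapse onto the same cycle
    set (e.g. every-10-years equals once-per-lifetime from age 62), so
    only the first strategy of each distinct schedule is kept.
    """
    seen: dict[frozenset, Strategy] = {}
    out = []
    for s in menu:
        key = frozenset(screening_cycles(s, initial_mean_age, horizon_cycles))
        if s.interval == "none" or key not in seen:
            seen[key] = s
            out.append(s)
    return out


@dataclass(frozen=True)
class ScreeningParams:
    """Test characteristics, compliance and detection behaviour."""

    compliance_screening: float = 0.49
    compliance_reexamination: float = 0.67
    sens_ec: float = 0.96
    spec_ec: float = 0.90
    sens_gc: float = 0.89
    spec_gc: float = 1.00
    complication_rate: float = 0.00009
    self_exam_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SELF_EXAM))
    treatment_compliance: Mapping[str, float] = field(default_factory=dict)
    fp_disutility: float = 0.001

    def __post_init__(self) -> None:
        probs = [self.compliance_screening, self.compliance_reexamination,
                 self.sens_ec, self.spec_ec, self.sens_gc, self.spec_gc,
                 self.complication_rate,
                 *self.self_exam_probs.values(),
                 *self.treatment_compliance.values()]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise StrategyError(f"probability {p} outside [0, 1]")

    def sensitivity(self, organ: str) -> float:
        return self.sens_ec if organ == "esophagus" else self.sens_gc

    def specificity(self, organ: str) -> float:
        return self.spec_ec if organ == "esophagus" else self.spec_gc


@dataclass
class ScreeningTally:
    """Countable events and one-time costs from a single cycle."""

    invited: float = 0.0
    attendees: float = 0.0
    true_positives: float = 0.0
    false_positives: float = 0.0
    complications: float = 0.0
    reexaminations: float = 0.0
    treated: float = 0.0
    self_detected: float = 0.0
    cost_mobilization: float = 0.0
    cost_endoscopy: float = 0.0
    cost_complication: float = 0.0
    cost_treatment: float = 0.0
    disutility: float = 0.0

    @property
    def event_cost(self) -> float:
        return (self.cost_mobilization + self.cost_endoscopy +
                self.cost_complication + self.cost_treatment)

    def add(self, other: "ScreeningTally") -> None:
        for name in self.__dataclass_fields__:
            setattr(self, name, getattr(self, name) + getattr(other, name))


def _check_occupancy(occupancy: np.ndarray) -> np.ndarray:
    occupancy = np.asarray(occupancy, dtype=float)
    if np.any(occupancy < -1e-9):
        raise StrategyError("negative occupancy mass")
    return occupancy


def apply_screening_event(occupancy: np.ndarray, space: StateSpace,
                          params: ScreeningParams, econ
                          ) -> tuple[np.ndarray, ScreeningTally,
                                     np.ndarray]:
    """One population screening round.

    Everyone alive and not already in a detected or posttreatment state
    is invited (incurring the per-capita mobilization cost); a fraction
    ``compliance_screening`` attends and is examined (endoscopy cost).
    Attendees with an undetected lesion move to the detected state with
    the organ-specific sensitivity — screen-found low-grade lesions only
    enter the detected (surveillance) state for the reexamination-
    compliant fraction.  Attendees without disease in an organ yield a
    false positive at one minus that organ's specificity, costing one
    reexamination endoscopy and a small utility decrement.  Endoscopy
    complications accrue per attendee.

    Returns (new occupancy, tally, newly detected mass per state).
    """
    occ = _check_occupancy(occupancy).copy()
    tally = ScreeningTally()
    new_detections = np.zeros_like(occ)

    invited_idx = [space.idx("normal")] + space.undetected_indices()
    tally.invited = float(occ[invited_idx].sum())
    tally.cost_mobilization = tally.invited * econ.mobilization_cost

    c = params.compliance_screening
    attendees_total = tally.invited * c
    tally.attendees = attendees_total
    tally.cost_endoscopy = attendees_total * econ.endoscopy_cost

    # true positives: undetected -> detected at organ sensitivity
    for u_idx, d_idx, st in space.detection_pairs():
        attending = occ[u_idx] * c
        found = attending * params.sensitivity(st.organ)
        if st.stage in LOW_GRADE_STAGES:
            # only the surveillance-compliant fraction is retained in care
            found *= params.compliance_reexamination
        occ[u_idx] -= found
        occ[d_idx] += found
        new_detections[d_idx] += found
        tally.true_positives += found

    # false positives: each attendee is examined for both organs and can
    # falsely test positive for any organ where no lesion is present
    fp = occ[space.idx("normal")] * c * \
        (1.0 - params.spec_ec * params.spec_gc)
    for u_idx, _, st in space.detection_pairs():
        other = "stomach" if st.organ == "esophagus" else "esophagus"
        fp += occupancy[u_idx] * c * (1.0 - params.specificity(other))
    tally.false_positives = float(fp)
    tally.reexaminations = float(fp)
    tally.cost_endoscopy += fp * econ.endoscopy_cost
    tally.disutility = fp * params.fp_disutility

    tally.complications = attendees_total * params.complication_rate
    tally.cost_complication = tally.complications * econ.complication_cost
    return occ, tally, new_detections


def apply_self_detection(occupancy: np.ndarray, space: StateSpace,
                         params: ScreeningParams
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Symptom-driven diagnosis, applied every cycle.

    Undetected severe dysplasia/CIS and HGIN/CIS, early cancer and
    advanced cancer move to their detected state at the tier-specific
    annual probability; low-grade lesions are asymptomatic and never
    self-detected.  Returns (new occupancy, newly detected mass).
    """
    occ = _check_occupancy(occupancy).copy()
    new_detections = np.zeros_like(occ)
    for u_idx, d_idx, st in space.detection_pairs():
        tier = _SELF_EXAM_TIER.get(st.stage)
        if tier is None:
            continue
        p = params.self_exam_probs.get(tier, 0.0)
        moved = occ[u_idx] * p
        occ[u_idx] -= moved
        occ[d_idx] += moved
        new_detections[d_idx] += moved
    return occ, new_detections


def apply_treatment(occupancy: np.ndarray, newly_detected: np.ndarray,
                    space: StateSpace, params: ScreeningParams, econ
                    ) -> tuple[np.ndarray, ScreeningTally]:
    """Offer treatment to mass newly diagnosed in a treatable stage.

    The stage-specific compliant fraction moves to the matching
    posttreatment state and is charged the stage's initial treatment
    cost; the rest stays detected-untreated under natural history.
    """
    occ = _check_occupancy(occupancy).copy()
    tally = ScreeningTally()
    for d_idx, (pt_idx, key) in space.treatable_detected().items():
        eligible = min(float(newly_detected[d_idx]), float(occ[d_idx]))
        if eligible <= 0.0:
            continue
        if key not in params.treatment_compliance:
            raise StrategyError(
                f"no treatment compliance entry for stage {key!r}")
        treated = eligible * params.treatment_compliance[key]
        occ[d_idx] -= treated
        occ[pt_idx] += treated
        tally.treated += treated
        tally.cost_treatment += treated * econ.initial_treatment[key]
    return occ, tally


def surveillance_cost(occupancy: np.ndarray, space: StateSpace,
                      econ) -> float:
    """Annual reexamination endoscopy cost for surveillance states."""
    idx = space.surveillance_indices()
    return float(occupancy[idx].sum()) * econ.endoscopy_cost
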