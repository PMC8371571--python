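"""Cost and utility parameters and per-cycle reward computation.

Costs are in 2019 US dollars, converted from renminbi at the 2019 rate
of 6.8968 CNY per USD, and taken from the health-care system
perspective (no productivity or travel costs).  Utilities are
stage-level scores in [0, 1]; detection status and posttreatment status
do not change a stage's utility.  Annual health-care costs accrue only
while a person is in care: detected severe dysplasia/CIS or HGIN/CIS,
detected cancer, or any posttreatment state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .state_space import StateSpace, stage_key

DEFAULT_EXCHANGE_RATE = 6.8968  # CNY per 2019 USD


class EconError(ValueError):
    """Invalid economic configuration."""


@dataclass(frozen=True)
class EconParams:
    """All cost and utility inputs, expanded over a state space.

    ``initial_treatment`` and the per-state maps are keyed by the short
    stage keys (``ec_sev`` ... ``gc_adv``) and state ids respectively.
    """

    mobilization_cost: float
    endoscopy_cost: float
    complication_cost: float
    initial_treatment: Mapping[str, float]
    annual_cost_by_state: Mapping[str, float]
    utilities_by_state: Mapping[str, float]
    exchange_rate: float = DEFAULT_EXCHANGE_RATE

    def __post_init__(self) -> None:
        for name, v in (("mobilization", self.mobilization_cost),
                        ("endoscopy", self.endoscopy_cost),
                        ("complication", self.complication_cost)):
            if v < 0:
                raise EconError(f"negative {name} cost")
        for k, v in self.initial_treatment.items():
            if v < 0:
                raise EconError(f"negative initial treatment cost for {k}")
        for k, u in self.utilities_by_state.items():
            if not 0.0 <= u <= 1.0:
                raise EconError(f"utility for {k} outside [0, 1]")
        if self.utilities_by_state.get("normal") != 1.0:
            raise EconError("utility of normal must be 1")
        if self.utilities_by_state.get("death") != 0.0:
            raise EconError("utility of death must be 0")
        if self.exchange_rate <= 0:
            raise EconError("exchange rate must be positive")

    def utility_vector(self, space: StateSpace) -> np.ndarray:
        try:
            return np.array([self.utilities_by_state[s.id]
                             for s in space.states])
        except KeyError as exc:
            raise EconError(f"missing utility for state {exc}") from None

    def annual_cost_vector(self, space: StateSpace) -> np.ndarray:
        return np.array([self.annual_cost_by_state.get(s.id, 0.0)
                         for s in space.states])


def build_econ_params(values: Mapping[str, float],
                      space: StateSpace) -> EconParams:
    """Expand flat named values into per-state utility/cost maps.

    Stage-level utilities and annual costs apply to the undetected,
    detected and posttreatment variants of a stage alike; annual costs
    are only charged for states in care (detected treatable stages,
    detected cancer, posttreatment).
    """
    stage_utility = {
        "ec_mild": values["utility_ec_mild"],
        "ec_mod": values["utility_ec_mod"],
        "ec_sev": values["utility_ec_sev"],
        "ec_early": values["utility_ec_early"],
        "ec_adv": values["utility_ec_adv"],
        "gc_lgin": values["utility_gc_lgin"],
        "gc_hgin": values["utility_gc_hgin"],
        "gc_early": values["utility_gc_early"],
        "gc_adv": values["utility_gc_adv"],
    }
    stage_annual = {
        "ec_sev": values["cost_annual_ec_sev"],
        "ec_early": values["cost_annual_ec_early"],
        "ec_adv": values["cost_annual_ec_adv"],
        "gc_hgin": values["cost_annual_gc_hgin"],
        "gc_early": values["cost_annual_gc_early"],
        "gc_adv": values["cost_annual_gc_adv"],
    }
    utilities = {}
    annual = {}
    for s in space.states:
        if s.stage == "normal":
            utilities[s.id] = 1.0
        elif s.stage == "death":
            utilities[s.id] = 0.0
        else:
            key = stage_key(s.organ, s.stage)
            utilities[s.id] = stage_utility[key]
            in_care = s.detection == "detected" or \
                s.treatment == "posttreatment"
            if in_care and key in stage_annual:
                annual[s.id] = stage_annual[key]
    initial_treatment = {k: values[f"cost_treat_{k}"]
                         for k in ("ec_sev", "ec_early", "ec_adv",
                                   "gc_hgin", "gc_early", "gc_adv")}
    return EconParams(
        mobilization_cost=values["cost_mobilization"],
        endoscopy_cost=values["cost_endoscopy"],
        complication_cost=values["cost_complication"],
        initial_treatment=initial_treatment,
        annual_cost_by_state=annual,
        utilities_by_state=utilities,
        exchange_rate=values.get("exchange_rate", DEFAULT_EXCHANGE_RATE),
    )


def cycle_rewards(occupancy_halfcycle: np.ndarray, event_cost: float,
                  event_disutility: float, econ: EconParams,
                  space: StateSpace, cycle_length: float = 1.0
                  ) -> tuple[float, float]:
    """Undiscounted QALYs and cost accrued over one cycle.

    QALYs are the utility-weighted half-cycle-corrected occupancy minus
    event disutilities; costs are state annual health-care costs plus
    one-time event costs.
    """
    occ = np.asarray(occupancy_halfcycle, dtype=float)
    qalys = float(occ @ econ.utility_vector(space)) * cycle_length \
        - event_disutility
    cost = float(occ @ econ.annual_cost_vector(space)) * cycle_length \
        + event_cost
    return qalys, cost


def convert_currency(amount_cny: float,
                     rate: float = DEFAULT_EXCHANGE_RATE) -> float:
    """Convert renminbi to 2019 US dollars."""
    if rate <= 0:
        raise EconError("exchange rate must be positive")
    if amount_cny < 0:
        raise EconError("amount must be non-negative")
    return amount_cny / rate
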