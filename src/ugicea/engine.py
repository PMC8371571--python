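"""Closed-cohort Markov engine with discounting and half-cycle correction.

The whole cohort ages one year per cycle starting at the age band's
mean age and the simulation stops when the mean age reaches the
terminal age (90 by default).  Within each cycle the event order is:

    screening round (if offered) -> self-initiated detection ->
    treatment of new diagnoses -> natural-history transition with
    age-specific background mortality.

State rewards (utilities and annual health-care costs) use the
trapezoidal half-cycle correction — the average of start- and
end-of-cycle occupancy — and one-time event costs are discounted at
mid-cycle (t + 0.5), consistent with events spread through the year.
Mass newly arriving in a detected treatable state through the
transition matrix (surveillance progression, progression of untreated
detected cancer, posttreatment recurrence) is offered treatment at the
next cycle's treatment step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import EconParams
from .state_space import StateSpace, TransitionMatrix, validate_matrix
from .strategies import (ScreeningParams, ScreeningTally, Strategy,
                         apply_screening_event, apply_self_detection,
                         apply_treatment, screening_cycles,
                         surveillance_cost)

COST_CATEGORIES = ("mobilization", "endoscopy", "complication",
                   "initial_treatment", "annual_care")


class EngineError(ValueError):
    """Invalid engine input."""


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, age band and horizon."""

    size: float = 100_000
    initial_mean_age: int = 42
    terminal_mean_age: int = 90
    cycle_length: float = 1.0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise EngineError("cohort size must be positive")
        if self.terminal_mean_age < self.initial_mean_age:
            raise EngineError("terminal age before initial age")

    @property
    def horizon_cycles(self) -> int:
        return self.terminal_mean_age - self.initial_mean_age


@dataclass
class CohortTrace:
    """Per-cycle occupancy, rewards and event tallies."""

    state_ids: list[str]
    occupancy: np.ndarray          # (T+1, S); row 0 is the initial vector
    qalys: np.ndarray              # (T,) undiscounted
    qalys_discounted: np.ndarray
    costs: np.ndarray              # (T,) undiscounted, all categories
    costs_discounted: np.ndarray
    cost_by_category: pd.DataFrame  # (T x categories), discounted
    events: pd.DataFrame           # per-cycle tallies

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format occupancy (cycle, state, occupancy)."""
        T = self.occupancy.shape[0]
        return pd.DataFrame({
            "cycle": np.repeat(np.arange(T), len(self.state_ids)),
            "state": np.tile(self.state_ids, T),
            "occupancy": self.occupancy.ravel(),
        })


@dataclass(frozen=True)
class StrategyOutcome:
    """Lifetime discounted totals for one strategy."""

    strategy: str
    total_discounted_qalys: float
    total_discounted_cost: float
    total_qalys: float = 0.0
    total_cost: float = 0.0


def annual_prob_from_survival(survival: float, years: float = 5.0) -> float:
    """Constant annual mortality probability implied by an S-year survival.

    Solves (1 - p)^years = survival for p, i.e. p = 1 - S**(1/years).
    """
    if not 0.0 < survival <= 1.0:
        raise EngineError(f"survival {survival} outside (0, 1]")
    return 1.0 - survival ** (1.0 / years)


def overlay_background_mortality(matrix: np.ndarray, q_background: float,
                                 death_index: int,
                                 living_mask: np.ndarray | None = None
                                 ) -> np.ndarray:
    """Add an age-specific background death probability to every living row.

    Background mortality competes with state-specific transitions by
    proportional rescaling: non-death entries shrink by (1 - q) and the
    freed mass goes to death, so rows stay stochastic.
    """
    if not 0.0 <= q_background <= 1.0:
        raise EngineError(f"background probability {q_background} "
                          "outside [0, 1]")
    out = matrix.copy()
    n = matrix.shape[0]
    rows = np.ones(n, dtype=bool) if living_mask is None \
        else living_mask.copy()
    rows[death_index] = False
    out[rows] *= (1.0 - q_background)
    out[rows, death_index] = 1.0 - out[rows].sum(axis=1) \
        + out[rows, death_index]
    return out


def _lookup_background(life_table: pd.Series, age: int) -> float:
    try:
        return float(life_table.loc[age])
    except KeyError:
        raise EngineError(f"age {age} outside life-table support") from None


def run_cohort(space: StateSpace, matrix: TransitionMatrix,
               strategy: Strategy, screening_params: ScreeningParams,
               econ_params: EconParams, cohort_spec: CohortSpec,
               discount_rate: float, *, initial_occupancy: np.ndarray,
               life_table: pd.Series,
               event_timing: str = "midcycle",
               validate: bool = True
               ) -> tuple[CohortTrace, StrategyOutcome]:
    """Simulate one strategy over the cohort's lifetime horizon.

    ``initial_occupancy`` is the baseline prevalence vector (detected
    and posttreatment mass zero); ``life_table`` maps integer age to the
    annual background death probability.  ``event_timing`` selects
    whether one-time event costs are discounted at mid-cycle (default)
    or at cycle start.
    """
    if validate:
        report = validate_matrix(matrix, space)
        if not report:
            raise EngineError("invalid transition matrix: " +
                              "; ".join(report.issues))
    if not 0.0 <= discount_rate <= 0.08:
        warnings.warn(f"discount rate {discount_rate} outside the "
                      "0-8% range considered plausible", stacklevel=2)
    if event_timing not in ("midcycle", "start"):
        raise EngineError(f"unknown event timing {event_timing!r}")

    occ = np.asarray(initial_occupancy, dtype=float).copy()
    if occ.shape != (len(space),):
        raise EngineError("initial occupancy not aligned to state space")
    T = cohort_spec.horizon_cycles
    S = len(space)
    u_vec = econ_params.utility_vector(space)
    c_vec = econ_params.annual_cost_vector(space)
    death_idx = space.death_index
    treatable = space.treatable_detected()
    treat_idx = np.array(sorted(treatable), dtype=int)
    cycles = screening_cycles(strategy, cohort_spec.initial_mean_age, T)

    occupancy = np.zeros((T + 1, S))
    occupancy[0] = occ
    qalys = np.zeros(T)
    qalys_d = np.zeros(T)
    costs = np.zeros(T)
    costs_d = np.zeros(T)
    cost_cat = np.zeros((T, len(COST_CATEGORIES)))
    event_rows = []
    carry_new = np.zeros(S)  # matrix-driven new diagnoses from last cycle

    for t in range(T):
        age = cohort_spec.initial_mean_age + t
        occ_start = occ.copy()
        tally = ScreeningTally()
        new_det = carry_new

        if t in cycles:
            occ, sc_tally, found = apply_screening_event(
                occ, space, screening_params, econ_params)
            tally.add(sc_tally)
            new_det = new_det + found

        occ, self_det = apply_self_detection(occ, space, screening_params)
        tally.self_detected = float(self_det.sum())
        new_det = new_det + self_det

        # annual reexamination endoscopies for surveillance states
        reexam_cost = surveillance_cost(occ, space, econ_params)
        tally.cost_endoscopy += reexam_cost

        occ, tr_tally = apply_treatment(occ, new_det, space,
                                        screening_params, econ_params)
        tally.add(tr_tally)

        q_bg = _lookup_background(life_table, age)
        m_age = overlay_background_mortality(
            matrix.at_age(age), q_bg, death_idx, space.living_mask)
        occ_new = occ @ m_age
        # inflow into detected treatable states from *other* states is a
        # new diagnosis, treated next cycle
        carry_new = np.zeros(S)
        carry_new[treat_idx] = occ_new[treat_idx] \
            - occ[treat_idx] * m_age[treat_idx, treat_idx]
        occ = occ_new
        occupancy[t + 1] = occ

        occ_half = 0.5 * (occ_start + occ)
        q_t = float(occ_half @ u_vec) * cohort_spec.cycle_length \
            - tally.disutility
        annual_care = float(occ_half @ c_vec) * cohort_spec.cycle_length
        c_t = annual_care + tally.event_cost

        df_state = (1.0 + discount_rate) ** -(t + 0.5)
        df_event = df_state if event_timing == "midcycle" \
            else (1.0 + discount_rate) ** -t
        qalys[t] = q_t
        qalys_d[t] = q_t * df_state
        costs[t] = c_t
        costs_d[t] = annual_care * df_state + tally.event_cost * df_event
        cost_cat[t] = [tally.cost_mobilization * df_event,
                       tally.cost_endoscopy * df_event,
                       tally.cost_complication * df_event,
                       tally.cost_treatment * df_event,
                       annual_care * df_state]
        event_rows.append({
            "cycle": t, "age": age,
            "invited": tally.invited, "attendees": tally.attendees,
            "true_positives": tally.true_positives,
            "false_positives": tally.false_positives,
            "complications": tally.complications,
            "reexaminations": tally.reexaminations,
            "self_detected": tally.self_detected,
            "treated": tally.treated,
        })

    trace = CohortTrace(
        state_ids=space.ids,
        occupancy=occupancy,
        qalys=qalys, qalys_discounted=qalys_d,
        costs=costs, costs_discounted=costs_d,
        cost_by_category=pd.DataFrame(cost_cat, columns=COST_CATEGORIES),
        events=pd.DataFrame(event_rows),
    )
    outcome = StrategyOutcome(
        strategy=strategy.name,
        total_discounted_qalys=float(qalys_d.sum()),
        total_discounted_cost=float(costs_d.sum()),
        total_qalys=float(qalys.sum()),
        total_cost=float(costs.sum()),
    )
    return trace, outcome
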