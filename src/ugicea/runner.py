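"""Glue: evaluate the strategy menu for a parameter set and age band.

This is the surface the CEA, one-way and PSA layers drive: a runner is
a callable taking named parameter overrides and returning
(strategy, discounted QALYs, discounted cost) tuples for every strategy
in the menu, all evaluated on the same parameterization.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .economics import build_econ_params
from .engine import CohortSpec, run_cohort
from .params import ParameterSet
from .state_space import StateSpace, build_state_space
from .strategies import STRATEGY_MENU, Strategy, distinct_strategies
from .synthetic import build_transition_matrix, prevalence_from_values

AGE_BANDS = {
    "40-44": 42, "45-49": 47, "50-54": 52,
    "55-59": 57, "60-64": 62, "65-69": 67,
}
MEAN_AGES = tuple(AGE_BANDS.values())


def evaluate_strategies(pset: ParameterSet, initial_mean_age: int,
                        strategies: Sequence[Strategy] | None = None,
                        size: float = 100_000,
                        terminal_mean_age: int = 90,
                        space: StateSpace | None = None,
                        trim_menu: bool = True,
                        ) -> list[tuple[str, float, float]]:
    """Run every strategy on one parameter set and age band.

    Returns (name, total discounted QALYs, total discounted cost)
    tuples.  When ``trim_menu`` is set, strategies whose screening
    schedule collapses onto a cheaper one at this initial age (e.g.
    every-10-years at mean age 62 equals once-per-lifetime) are
    dropped, mirroring how result tables are usually laid out.
    """
    space = space or build_state_space()
    spec = CohortSpec(size=size, initial_mean_age=initial_mean_age,
                      terminal_mean_age=terminal_mean_age)
    if strategies is None:
        strategies = (distinct_strategies(initial_mean_age,
                                          spec.horizon_cycles)
                      if trim_menu else STRATEGY_MENU)
    matrix = build_transition_matrix(pset.values, space)
    screening = pset.screening_params()
    econ = build_econ_params(pset.values, space)
    prevalence = prevalence_from_values(pset.values, space, size)
    life = pset.life_table
    out = []
    for strat in strategies:
        _, outcome = run_cohort(space, matrix, strat, screening, econ,
                                spec, pset.discount_rate,
                                initial_occupancy=prevalence,
                                life_table=life, validate=False)
        out.append((strat.name, outcome.total_discounted_qalys,
                    outcome.total_discounted_cost))
    return out


def make_runner(pset: ParameterSet, initial_mean_age: int,
                strategies: Sequence[Strategy] | None = None,
                size: float = 100_000,
                terminal_mean_age: int = 90):
    """Close over a base parameter set; overrides re-parameterize it."""
    space = build_state_space()
    strategies = tuple(strategies) if strategies is not None else None

    def runner(overrides: Mapping[str, float]
               ) -> list[tuple[str, float, float]]:
        current = pset.with_values(overrides) if overrides else pset
        return evaluate_strategies(current, initial_mean_age,
                                   strategies=strategies, size=size,
                                   terminal_mean_age=terminal_mean_age,
                                   space=space)

    return runner
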