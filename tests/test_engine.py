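import numpy as np
import pandas as pd
import pytest

from ugicea.economics import build_econ_params
from ugicea.engine import (CohortSpec, EngineError,
                           annual_prob_from_survival,
                           overlay_background_mortality, run_cohort)
from ugicea.state_space import TransitionMatrix
from ugicea.strategies import get_strategy
from ugicea.synthetic import (build_transition_matrix,
                              prevalence_from_values)


class TestAnnualProbFromSurvival:
    # overall five-year survival 30.3% (EC) and 35.1% (GC) imply annual
    # mortality probabilities of 0.2124 and 0.1889
    @pytest.mark.parametrize("survival, expected", [
        (1.0, 0.0),
        (0.303, 0.2124),
        (0.351, 0.1889),
    ])
    def test_known_conversions(self, survival, expected):
        assert annual_prob_from_survival(survival) == \
            pytest.approx(expected, abs=5e-5)

    def test_round_trip(self):
        p = annual_prob_from_survival(0.86)
        assert (1 - p) ** 5 == pytest.approx(0.86)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(EngineError):
            annual_prob_from_survival(bad)


class TestBackgroundOverlay:
    def test_zero_background_is_identity(self):
        m = np.array([[0.9, 0.1, 0.0], [0.0, 0.8, 0.2], [0.0, 0.0, 1.0]])
        out = overlay_background_mortality(m, 0.0, death_index=2)
        np.testing.assert_allclose(out, m)

    def test_proportional_rescaling(self):
        m = np.array([[0.9, 0.1, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        out = overlay_background_mortality(m, 0.01, death_index=2)
        np.testing.assert_allclose(out[0], [0.891, 0.099, 0.01])
        np.testing.assert_allclose(out.sum(axis=1), 1.0)

    def test_certain_background_death(self):
        m = np.array([[0.9, 0.1, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        out = overlay_background_mortality(m, 1.0, death_index=2)
        np.testing.assert_allclose(out[:2, 2], 1.0)

    def test_competing_cancer_mortality_compounds(self):
        # prior death entry d combines as q + (1-q)d
        m = np.array([[0.8, 0.0, 0.2], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        out = overlay_background_mortality(m, 0.1, death_index=2)
        assert out[0, 2] == pytest.approx(0.1 + 0.9 * 0.2)


def run_default(pset, space, strategy_name="no_screening", age=62,
                terminal=90, discount=None, econ=None, life_table=None,
                size=100_000.0, sp=None):
    matrix = build_transition_matrix(pset.values, space)
    screening = sp or pset.screening_params()
    econ = econ or build_econ_params(pset.values, space)
    prev = prevalence_from_values(pset.values, space, size)
    life = life_table if life_table is not None else pset.life_table
    rate = pset.discount_rate if discount is None else discount
    return run_cohort(space, matrix, get_strategy(strategy_name),
                      screening, econ,
                      CohortSpec(size=size, initial_mean_age=age,
                                 terminal_mean_age=terminal),
                      rate, initial_occupancy=prev, life_table=life)


class TestRunCohort:
    def test_constant_occupancy_half_cycle_identity(self, space,
                                                    neutral_econ, pset,
                                                    zero_life_table):
        """With everyone healthy, no mortality, utility 1 and no
        discounting, 10 cycles accrue exactly 10 x cohort size QALYs."""
        matrix = TransitionMatrix(np.eye(26), space.ids)
        prev = np.zeros(26)
        prev[space.idx("normal")] = 100_000.0
        _, outcome = run_cohort(
            space, matrix, get_strategy("no_screening"),
            pset.screening_params(), neutral_econ,
            CohortSpec(initial_mean_age=42, terminal_mean_age=52),
            0.0, initial_occupancy=prev, life_table=zero_life_table)
        assert outcome.total_discounted_qalys == pytest.approx(1_000_000.0)
        assert outcome.total_discounted_cost == 0.0

    def test_one_time_costs_discounted_at_mid_cycle(self, space, pset,
                                                    neutral_econ,
                                                    zero_life_table):
        """A screening round at cycle t contributes cost/(1+r)^(t+0.5)."""
        from dataclasses import replace
        econ = replace(neutral_econ, mobilization_cost=2.0)
        matrix = TransitionMatrix(np.eye(26), space.ids)
        prev = np.zeros(26)
        prev[space.idx("normal")] = 100_000.0
        r = 0.05
        trace, _ = run_cohort(
            space, matrix, get_strategy("every_10y"),
            pset.screening_params(), econ,
            CohortSpec(initial_mean_age=42, terminal_mean_age=62),
            r, initial_occupancy=prev, life_table=zero_life_table)
        for t in (0, 10):
            undiscounted = trace.costs[t]
            assert undiscounted == pytest.approx(200_000.0)
            assert trace.costs_discounted[t] == pytest.approx(
                undiscounted * (1 + r) ** -(t + 0.5))

    def test_event_costs_at_cycle_start_when_configured(self, space, pset,
                                                        neutral_econ,
                                                        zero_life_table):
        from dataclasses import replace
        econ = replace(neutral_econ, mobilization_cost=2.0)
        matrix = TransitionMatrix(np.eye(26), space.ids)
        prev = np.zeros(26)
        prev[space.idx("normal")] = 100_000.0
        trace, _ = run_cohort(
            space, matrix, get_strategy("once_per_lifetime"),
            pset.screening_params(), econ,
            CohortSpec(initial_mean_age=42, terminal_mean_age=52),
            0.05, initial_occupancy=prev, life_table=zero_life_table,
            event_timing="start")
        assert trace.costs_discounted[0] == pytest.approx(trace.costs[0])

    def test_matrix_power_closed_form_without_events(self, space, pset,
                                                     neutral_econ,
                                                     zero_life_table):
        """Time-homogeneous no-screening dynamics equal initial
        occupancy times the t-th matrix power."""
        from ugicea.strategies import ScreeningParams
        sp = ScreeningParams(
            self_exam_probs={"severe": 0.0, "early": 0.0, "advanced": 0.0},
            treatment_compliance=pset.screening_params()
            .treatment_compliance)
        matrix = build_transition_matrix(pset.values, space)
        prev = prevalence_from_values(pset.values, space, 100_000.0)
        trace, _ = run_cohort(
            space, matrix, get_strategy("no_screening"), sp, neutral_econ,
            CohortSpec(initial_mean_age=42, terminal_mean_age=52),
            0.0, initial_occupancy=prev, life_table=zero_life_table)
        for t in (1, 5, 10):
            expected = prev @ np.linalg.matrix_power(matrix.values, t)
            np.testing.assert_allclose(trace.occupancy[t], expected,
                                       atol=1e-9 * prev.sum())

    def test_mass_conserved_and_death_monotone(self, space, pset):
        trace, _ = run_default(pset, space, "every_2y", age=42)
        sums = trace.occupancy.sum(axis=1)
        np.testing.assert_allclose(sums, 100_000.0, atol=1e-6)
        death = trace.occupancy[:, space.death_index]
        assert np.all(np.diff(death) >= -1e-9)

    def test_discounted_totals_non_increasing_in_rate(self, space, pset):
        results = [run_default(pset, space, "every_2y", age=62,
                               discount=r)[1] for r in (0.0, 0.03, 0.05)]
        qalys = [o.total_discounted_qalys for o in results]
        costs = [o.total_discounted_cost for o in results]
        assert qalys == sorted(qalys, reverse=True)
        assert costs == sorted(costs, reverse=True)

    def test_zero_horizon_accumulates_nothing(self, space, pset):
        trace, outcome = run_default(pset, space, age=67, terminal=67)
        assert trace.occupancy.shape[0] == 1
        assert outcome.total_discounted_qalys == 0.0
        assert outcome.total_discounted_cost == 0.0

    def test_discount_rate_outside_range_warns(self, space, pset):
        with pytest.warns(UserWarning):
            run_default(pset, space, age=67, discount=0.2)

    def test_age_outside_life_table_raises(self, space, pset):
        short_table = pd.Series(0.001, index=range(40, 60))
        with pytest.raises(EngineError):
            run_default(pset, space, age=42, life_table=short_table)

    def test_invalid_matrix_rejected(self, space, pset,
                                     zero_life_table, neutral_econ):
        vals = np.eye(26)
        vals[0, 0] = 0.5
        matrix = TransitionMatrix(vals, space.ids)
        prev = np.zeros(26)
        prev[0] = 1.0
        with pytest.raises(EngineError):
            run_cohort(space, matrix, get_strategy("no_screening"),
                       pset.screening_params(), neutral_econ,
                       CohortSpec(initial_mean_age=42,
                                  terminal_mean_age=52),
                       0.05, initial_occupancy=prev,
                       life_table=zero_life_table)

    def test_blind_screening_changes_nothing_but_costs(self, space, pset):
        """Zero test sensitivity: trajectories match no screening;
        only false-positive costs and disutility differ."""
        sp_blind = pset.screening_params()
        from dataclasses import replace
        sp_blind = replace(sp_blind, sens_ec=0.0, sens_gc=0.0)
        trace_b, out_b = run_default(pset, space, "every_2y", age=62,
                                     sp=sp_blind)
        trace_n, out_n = run_default(pset, space, "no_screening", age=62)
        np.testing.assert_allclose(trace_b.occupancy, trace_n.occupancy,
                                   atol=1e-6)
        assert out_b.total_discounted_cost > out_n.total_discounted_cost
        assert out_b.total_discounted_qalys < out_n.total_discounted_qalys
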