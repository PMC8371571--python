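import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from ugicea.strategies import (ScreeningParams, Strategy,
                               StrategyError, apply_screening_event,
                               apply_self_detection, apply_treatment,
                               distinct_strategies, get_strategy,
                               screening_cycles)

MEAN_AGES = (42, 47, 52, 57, 62, 67)


def make_params(pset, **overrides):
    base = pset.screening_params()
    fields = {f: getattr(base, f) for f in base.__dataclass_fields__}
    fields.update(overrides)
    return ScreeningParams(**fields)


class TestScreeningCycles:
    def test_every_2y_at_67_offers_rounds_at_67_and_69(self):
        # 71 would fall outside the 40-69 eligibility window
        assert screening_cycles(get_strategy("every_2y"), 67, 23) == {0, 2}

    def test_no_screening_has_no_rounds(self):
        for age in MEAN_AGES:
            assert screening_cycles(get_strategy("no_screening"),
                                    age, 48) == set()

    def test_every_10y_at_62_collapses_to_once(self):
        assert screening_cycles(get_strategy("every_10y"), 62, 28) == {0}
        assert screening_cycles(get_strategy("once_per_lifetime"),
                                62, 28) == {0}

    def test_unknown_interval_rejected(self):
        with pytest.raises(StrategyError):
            Strategy("weekly", 0)

    @given(age=hst.sampled_from(MEAN_AGES))
    @settings(deadline=None)
    def test_shorter_intervals_never_screen_less(self, age):
        horizon = 90 - age
        sizes = [len(screening_cycles(get_strategy(n), age, horizon))
                 for n in ("every_2y", "every_3y", "every_5y",
                           "every_10y", "once_per_lifetime")]
        assert sizes == sorted(sizes, reverse=True)

    @given(age=hst.sampled_from(MEAN_AGES),
           k=hst.sampled_from([2, 3, 5]))
    @settings(deadline=None)
    def test_interval_multiples_are_nested(self, age, k):
        horizon = 90 - age
        base = screening_cycles(Strategy("k", k), age, horizon)
        doubled = screening_cycles(Strategy("2k", 2 * k), age, horizon) \
            if 2 * k in (2, 3, 5, 10) else set()
        assert doubled <= base

    def test_menu_trimming_matches_reported_age_blocks(self):
        # which strategy rows are distinct per initial age band
        expected = {
            42: 6, 47: 6, 52: 6, 57: 6,
            62: 5,   # every-10-years collapses onto once per lifetime
            67: 3,   # only once and every-2-years remain distinct
        }
        for age, n in expected.items():
            assert len(distinct_strategies(age, 90 - age)) == n


class TestScreeningEvent:
    def test_perfect_test_detects_everything_without_false_positives(
            self, space, pset, econ):
        params = make_params(pset, sens_ec=1.0, spec_ec=1.0, sens_gc=1.0,
                             spec_gc=1.0, compliance_screening=1.0,
                             compliance_reexamination=1.0)
        occ = np.zeros(len(space))
        occ[space.idx("ec_early_u")] = 500.0
        occ[space.idx("gc_adv_u")] = 300.0
        occ[space.idx("normal")] = 99_200.0
        new_occ, tally, found = apply_screening_event(occ, space, params,
                                                      econ)
        assert new_occ[space.idx("ec_early_u")] == 0.0
        assert new_occ[space.idx("ec_early_d")] == 500.0
        assert new_occ[space.idx("gc_adv_d")] == 300.0
        assert tally.false_positives == 0.0
        assert found.sum() == pytest.approx(800.0)

    def test_zero_compliance_leaves_occupancy_unchanged(self, space, pset,
                                                        econ):
        params = make_params(pset, compliance_screening=0.0)
        occ = np.full(len(space), 100.0)
        occ[space.death_index] = 0.0
        new_occ, tally, _ = apply_screening_event(occ, space, params, econ)
        np.testing.assert_allclose(new_occ, occ)
        assert tally.attendees == 0.0
        assert tally.cost_endoscopy == 0.0
        # population-wide mobilization is still charged per invitee
        assert tally.cost_mobilization == pytest.approx(
            tally.invited * econ.mobilization_cost)

    def test_expected_complications_at_published_rate(self, space, pset,
                                                      econ):
        params = make_params(pset, compliance_screening=1.0)
        occ = np.zeros(len(space))
        occ[space.idx("normal")] = 100_000.0
        _, tally, _ = apply_screening_event(occ, space, params, econ)
        assert tally.complications == pytest.approx(9.0)

    def test_mass_conserved(self, space, pset, econ):
        params = make_params(pset)
        rng = np.random.default_rng(7)
        occ = rng.uniform(0, 1000, len(space))
        new_occ, _, _ = apply_screening_event(occ, space, params, econ)
        assert new_occ.sum() == pytest.approx(occ.sum(), abs=1e-6)
        assert np.all(new_occ >= 0)

    def test_negative_occupancy_rejected(self, space, pset, econ):
        occ = np.zeros(len(space))
        occ[0] = -1.0
        with pytest.raises(StrategyError):
            apply_screening_event(occ, space, make_params(pset), econ)


class TestSelfDetection:
    def test_advanced_cancer_detected_at_70_percent(self, space, pset):
        occ = np.zeros(len(space))
        occ[space.idx("ec_adv_u")] = 1000.0
        new_occ, _ = apply_self_detection(occ, space,
                                          pset.screening_params())
        assert new_occ[space.idx("ec_adv_d")] == pytest.approx(700.0)
        assert new_occ[space.idx("ec_adv_u")] == pytest.approx(300.0)

    def test_low_grade_lesions_never_self_detected(self, space, pset):
        occ = np.zeros(len(space))
        for sid in ("ec_mild_u", "ec_mod_u", "gc_lgin_u"):
            occ[space.idx(sid)] = 1000.0
        new_occ, found = apply_self_detection(occ, space,
                                              pset.screening_params())
        np.testing.assert_allclose(new_occ, occ)
        assert found.sum() == 0.0

    def test_zero_probabilities_are_identity(self, space, pset):
        params = make_params(pset, self_exam_probs={
            "severe": 0.0, "early": 0.0, "advanced": 0.0})
        rng = np.random.default_rng(3)
        occ = rng.uniform(0, 100, len(space))
        new_occ, _ = apply_self_detection(occ, space, params)
        np.testing.assert_allclose(new_occ, occ)


class TestTreatment:
    def test_compliant_fraction_moves_to_posttreatment(self, space, pset,
                                                       econ):
        occ = np.zeros(len(space))
        occ[space.idx("gc_early_d")] = 1000.0
        newly = occ.copy()
        new_occ, tally = apply_treatment(occ, newly, space,
                                         pset.screening_params(), econ)
        assert new_occ[space.idx("gc_early_pt")] == pytest.approx(900.0)
        assert new_occ[space.idx("gc_early_d")] == pytest.approx(100.0)
        assert tally.cost_treatment == pytest.approx(
            900.0 * econ.initial_treatment["gc_early"])

    def test_hgin_compliance(self, space, pset, econ):
        occ = np.zeros(len(space))
        occ[space.idx("gc_hgin_d")] = 1000.0
        new_occ, _ = apply_treatment(occ, occ.copy(), space,
                                     pset.screening_params(), econ)
        assert new_occ[space.idx("gc_hgin_pt")] == pytest.approx(545.5)

    def test_full_compliance_treats_all_new_detections(self, space, pset,
                                                       econ):
        params = make_params(pset, treatment_compliance={
            k: 1.0 for k in ("ec_sev", "ec_early", "ec_adv",
                             "gc_hgin", "gc_early", "gc_adv")})
        occ = np.zeros(len(space))
        for d_idx in space.treatable_detected():
            occ[d_idx] = 50.0
        new_occ, _ = apply_treatment(occ, occ.copy(), space, params, econ)
        for d_idx, (pt_idx, _) in space.treatable_detected().items():
            assert new_occ[d_idx] == 0.0
            assert new_occ[pt_idx] == 50.0

    def test_previously_detected_mass_stays_untreated(self, space, pset,
                                                      econ):
        occ = np.zeros(len(space))
        occ[space.idx("ec_adv_d")] = 1000.0
        new_occ, tally = apply_treatment(occ, np.zeros_like(occ), space,
                                         pset.screening_params(), econ)
        np.testing.assert_allclose(new_occ, occ)
        assert tally.treated == 0.0

    def test_missing_compliance_entry_rejected(self, space, pset, econ):
        params = make_params(pset, treatment_compliance={"ec_sev": 0.7})
        occ = np.zeros(len(space))
        occ[space.idx("gc_early_d")] = 10.0
        with pytest.raises(StrategyError):
            apply_treatment(occ, occ.copy(), space, params, econ)
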