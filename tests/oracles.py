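"""Independent individual-level microsimulation oracle.

Re-implements the cohort model as a Monte-Carlo simulation of discrete
individuals — every screening attendance, detection, treatment choice
and state transition is a Bernoulli/categorical draw — without sharing
any propagation code with the cohort engine.  The engine is the
mean-field limit of this process, so for matching inputs the engine's
per-capita discounted QALYs and costs must agree with the
microsimulation mean within Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ugicea.economics import EconParams
from ugicea.state_space import LOW_GRADE_STAGES, StateSpace
from ugicea.strategies import ScreeningParams, Strategy, screening_cycles
from ugicea.engine import CohortSpec, overlay_background_mortality


@dataclass
class MicrosimResult:
    qalys: np.ndarray  # per-individual discounted QALYs
    costs: np.ndarray  # per-individual discounted costs

    @property
    def mean_qalys(self) -> float:
        return float(self.qalys.mean())

    @property
    def mean_costs(self) -> float:
        return float(self.costs.mean())

    def se_qalys(self) -> float:
        return float(self.qalys.std(ddof=1) / np.sqrt(len(self.qalys)))

    def se_costs(self) -> float:
        return float(self.costs.std(ddof=1) / np.sqrt(len(self.costs)))


def run_microsim(space: StateSpace, matrix, strategy: Strategy,
                 sp: ScreeningParams, econ: EconParams,
                 cohort_spec: CohortSpec, discount_rate: float,
                 initial_occupancy: np.ndarray, life_table,
                 n_individuals: int, seed: int) -> MicrosimResult:
    rng = np.random.default_rng(seed)
    n = n_individuals
    S = len(space)
    probs = np.asarray(initial_occupancy, float)
    probs = probs / probs.sum()
    state = rng.choice(S, size=n, p=probs)

    u_vec = econ.utility_vector(space)
    c_vec = econ.annual_cost_vector(space)
    death_idx = space.death_index
    pairs = space.detection_pairs()
    treatable = space.treatable_detected()
    surveillance = np.zeros(S, dtype=bool)
    surveillance[space.surveillance_indices()] = True
    invited_states = np.zeros(S, dtype=bool)
    invited_states[space.idx("normal")] = True
    for u_idx, _, _ in pairs:
        invited_states[u_idx] = True

    T = cohort_spec.horizon_cycles
    cycles = screening_cycles(strategy, cohort_spec.initial_mean_age, T)
    qalys = np.zeros(n)
    costs = np.zeros(n)
    newly = np.zeros(n, dtype=bool)  # new diagnosis awaiting treatment

    for t in range(T):
        age = cohort_spec.initial_mean_age + t
        df = (1.0 + discount_rate) ** -(t + 0.5)
        s_pre = state.copy()

        if t in cycles:
            invited = invited_states[s_pre]
            costs[invited] += econ.mobilization_cost * df
            attend = invited & (rng.random(n) < sp.compliance_screening)
            costs[attend] += econ.endoscopy_cost * df
            for u_idx, d_idx, st in pairs:
                p_det = sp.sensitivity(st.organ)
                if st.stage in LOW_GRADE_STAGES:
                    p_det *= sp.compliance_reexamination
                hit = attend & (s_pre == u_idx) & (rng.random(n) < p_det)
                state[hit] = d_idx
                if d_idx in treatable:
                    newly |= hit
            # false positives (per organ without a lesion) and
            # complications, applied on pre-screening state
            p_fp = np.zeros(S)
            p_fp[space.idx("normal")] = 1.0 - sp.spec_ec * sp.spec_gc
            for u_idx, _, st in pairs:
                other = "stomach" if st.organ == "esophagus" \
                    else "esophagus"
                p_fp[u_idx] = 1.0 - sp.specificity(other)
            fp = attend & (rng.random(n) < p_fp[s_pre])
            costs[fp] += econ.endoscopy_cost * df
            qalys[fp] -= sp.fp_disutility * df
            comp = attend & (rng.random(n) < sp.complication_rate)
            costs[comp] += econ.complication_cost * df

        # self-initiated examination on undetected mass, every cycle
        for u_idx, d_idx, st in pairs:
            tier = {"severe_dysplasia_cis": "severe", "hgin_cis": "severe",
                    "early_cancer": "early",
                    "advanced_cancer": "advanced"}.get(st.stage)
            if tier is None:
                continue
            p = sp.self_exam_probs.get(tier, 0.0)
            hit = (state == u_idx) & (rng.random(n) < p)
            state[hit] = d_idx
            if d_idx in treatable:
                newly |= hit

        # annual surveillance endoscopy for detected low-grade lesions
        costs[surveillance[state]] += econ.endoscopy_cost * df

        # treatment offered once per new diagnosis
        for d_idx, (pt_idx, key) in treatable.items():
            cand = newly & (state == d_idx)
            accept = cand & (rng.random(n) <
                             sp.treatment_compliance[key])
            state[accept] = pt_idx
            costs[accept] += econ.initial_treatment[key] * df
        newly[:] = False

        # natural-history transition with background mortality overlay
        q_bg = float(life_table.loc[age])
        m_age = overlay_background_mortality(
            matrix.at_age(age), q_bg, death_idx, space.living_mask)
        cum = np.cumsum(m_age, axis=1)
        s_before_move = state.copy()
        u = rng.random(n)
        for i in range(S):
            mask = s_before_move == i
            if mask.any():
                state[mask] = np.searchsorted(cum[i], u[mask],
                                              side="right")
        state = np.minimum(state, S - 1)
        arrived = (state != s_before_move) & \
            np.isin(state, list(treatable))
        newly |= arrived

        # trapezoidal half-cycle rewards on start/end-of-cycle states
        qalys += df * 0.5 * (u_vec[s_pre] + u_vec[state])
        costs += df * 0.5 * (c_vec[s_pre] + c_vec[state])

    return MicrosimResult(qalys=qalys, costs=costs)
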