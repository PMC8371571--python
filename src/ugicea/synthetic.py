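"""Complete, internally consistent parameter sets for the model.

Two kinds of inputs are assembled here.  The published base-case
estimates (screening compliance, test characteristics, complication
rate, self-initiated examination, treatment compliance, costs,
utilities, discount rate) come with ranges and uncertainty
distributions and are returned by :func:`default_table1_params`.

Natural-history transition probabilities, baseline lesion prevalences,
the detailed cost/utility expansion over states and the age-specific
background life table are not published at that level of detail, so
this module generates *synthetic* stand-ins: a row-stochastic
progression/regression matrix over both organ chains with
survival-derived cancer mortality, a baseline prevalence vector with
all lesion mass undetected, and a Gompertz-type adult life table.
These synthetic values are field-plausible defaults, clearly flagged in
the parameter-set ``source`` metadata; a user-supplied parameter file
in the same schema (see :meth:`ugicea.params.ParameterSet.from_yaml`)
drops in verbatim replacements.

Gamma cost distributions are parameterized as (shape, rate).  The
published rate constants are kept only through their shapes (which set
the coefficient of variation); each rate is anchored to shape/base so
the distribution mean equals the base-case cost exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import annual_prob_from_survival
from .params import ParameterSet
from .sensitivity import DistributionSpec, ParameterGroup
from .state_space import (StateSpace, TransitionMatrix,
                          build_state_space, validate_matrix)

UNIT_INTERVAL = (0.0, 1.0)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic generator.

    ``seed`` (when not None) jitters transition and prevalence defaults
    by +/-10% so distinct plausible parameter worlds can be generated
    deterministically; the scale factors shift lesion burden and
    progression speed wholesale; ``life_table_params`` are the annual
    background mortality hazard at age 40 and its exponential slope.
    """

    seed: int | None = None
    prevalence_scale: float = 1.0
    progression_scale: float = 1.0
    life_table_params: tuple[float, float] = (0.002, 0.09)

    def __post_init__(self) -> None:
        if self.prevalence_scale < 0 or self.progression_scale < 0:
            raise SyntheticError("scales must be non-negative")
        if any(p <= 0 for p in self.life_table_params):
            raise SyntheticError("life-table parameters must be positive")


def _tri(lo: float, mode: float, hi: float,
         domain=UNIT_INTERVAL) -> DistributionSpec:
    return DistributionSpec("triangular", (lo, mode, hi),
                            range=(lo, hi), domain=domain)


def _beta(a: float, b: float, lo: float, hi: float) -> DistributionSpec:
    return DistributionSpec("beta", (a, b), range=(lo, hi),
                            domain=UNIT_INTERVAL)


def _gamma_cost(shape: float, base: float) -> DistributionSpec:
    # rate anchored to shape/base: mean == base exactly
    return DistributionSpec("gamma", (shape, shape / base),
                            range=(0.5 * base, 1.5 * base),
                            domain=(0.0, float("inf")))


def _fixed(value: float, lo: float, hi: float,
           domain=None) -> DistributionSpec:
    return DistributionSpec("fixed", (value,), range=(lo, hi),
                            domain=domain)


def default_table1_params() -> tuple[dict[str, float],
                                     dict[str, DistributionSpec]]:
    """Published base-case values, ranges and distributions.

    Returns a (values, distributions) fragment covering screening and
    treatment compliance, test characteristics, complications,
    self-initiated examination probabilities, unit costs, utility
    scores and the discount rate.  Cost ranges are base +/-50%.
    """
    values: dict[str, float] = {}
    dists: dict[str, DistributionSpec] = {}

    def add(name, base, dist):
        values[name] = base
        dists[name] = dist

    add("compliance_screening", 0.49, _tri(0.30, 0.49, 0.80))
    add("compliance_reexamination", 0.67, _tri(0.40, 0.67, 0.90))
    add("sens_ec", 0.96, _tri(0.88, 0.96, 0.99))
    add("spec_ec", 0.90, _tri(0.59, 0.90, 1.00))
    add("sens_gc", 0.89, _tri(0.70, 0.89, 0.98))
    add("spec_gc", 1.00, _tri(0.90, 1.00, 1.00))
    add("complication_rate", 0.00009, _tri(0.0, 0.00009, 0.002))
    add("selfexam_severe", 0.01, _tri(0.005, 0.01, 0.02))
    add("selfexam_early", 0.20, _tri(0.10, 0.20, 0.40))
    add("selfexam_advanced", 0.70, _tri(0.56, 0.70, 0.90))

    add("treat_compliance_ec_sev", 0.7458,
        _beta(31.72, 10.81, 0.5625, 0.9654))
    add("treat_compliance_ec_early", 0.9405,
        _beta(8.17, 0.52, 0.7149, 1.0000))
    add("treat_compliance_ec_adv", 0.9643,
        _beta(16.99, 0.63, 0.8393, 1.0000))
    add("treat_compliance_gc_hgin", 0.5455,
        _beta(92.43, 77.01, 0.4425, 0.7746))
    add("treat_compliance_gc_early", 0.9000,
        _beta(12.41, 1.38, 0.6792, 1.0000))
    add("treat_compliance_gc_adv", 0.9643,
        _beta(16.99, 0.63, 0.8393, 1.0000))

    for name, base, shape in (
            ("cost_mobilization", 1.05, 0.16),
            ("cost_endoscopy", 47.87, 46.57),
            ("cost_complication", 113.68, 5.82),
            ("cost_treat_ec_sev", 1604.0, 3.33),
            ("cost_treat_ec_early", 7732.0, 2.33),
            ("cost_treat_ec_adv", 7320.0, 3.33),
            ("cost_treat_gc_hgin", 1423.0, 1.41),
            ("cost_treat_gc_early", 7548.0, 4.61),
            ("cost_treat_gc_adv", 7086.0, 5.96),
            ("cost_annual_ec_sev", 216.0, 1.22),
            ("cost_annual_ec_early", 367.0, 1.23),
            ("cost_annual_ec_adv", 342.0, 2.05),
            ("cost_annual_gc_hgin", 243.0, 1.24),
            ("cost_annual_gc_early", 409.0, 1.18),
            ("cost_annual_gc_adv", 435.0, 1.19)):
        add(name, base, _gamma_cost(shape, base))

    add("utility_ec_mild", 1.00, _tri(0.98, 1.00, 1.00))
    add("utility_ec_mod", 1.00, _tri(0.98, 1.00, 1.00))
    add("utility_ec_sev", 0.84, _beta(3.57, 0.68, 0.79, 0.89))
    add("utility_ec_early", 0.70, _beta(2.63, 1.13, 0.66, 0.74))
    add("utility_ec_adv", 0.61, _beta(1.12, 0.71, 0.56, 0.66))
    add("utility_gc_lgin", 1.00, _tri(0.98, 1.00, 1.00))
    add("utility_gc_hgin", 0.92, _beta(2.53, 0.22, 0.86, 0.99))
    add("utility_gc_early", 0.75, _beta(3.15, 1.05, 0.71, 0.78))
    add("utility_gc_adv", 0.57, _beta(1.35, 1.02, 0.53, 0.62))

    add("discount_rate", 0.05, _fixed(0.05, 0.0, 0.08))
    # a false-positive result costs a small, configurable utility
    # decrement; no published magnitude exists for it
    add("fp_disutility", 0.001, _fixed(0.001, 0.0, 0.002))
    return values, dists


#: synthetic natural-history defaults: annual transition probabilities,
#: five-year survival proportions, recurrence probabilities and baseline
#: prevalence proportions.  Chosen once as plausible values for high-risk
#: areas; not published estimates.
SYNTHETIC_DEFAULTS: dict[str, float] = {
    "tp_onset_ec": 0.004,
    "tp_onset_gc": 0.005,
    "tp_ec_mild_mod": 0.05,
    "tp_ec_mod_sev": 0.06,
    "tp_ec_sev_early": 0.18,
    "tp_ec_early_adv": 0.35,
    "tp_ec_mild_reg": 0.06,
    "tp_ec_mod_reg": 0.05,
    "tp_ec_sev_reg": 0.02,
    "tp_gc_lgin_hgin": 0.04,
    "tp_gc_hgin_early": 0.15,
    "tp_gc_early_adv": 0.35,
    "tp_gc_lgin_reg": 0.06,
    "tp_gc_hgin_reg": 0.02,
    # five-year survival: overall advanced-stage figures and
    # early-detection figures; treated-advanced is synthetic
    "surv5_ec_adv": 0.303,
    "surv5_gc_adv": 0.351,
    "surv5_ec_early": 0.86,
    "surv5_gc_early": 0.90,
    "surv5_ec_adv_treated": 0.40,
    "surv5_gc_adv_treated": 0.45,
    "recur_precancer": 0.01,
    "recur_early": 0.04,
    "recur_adv": 0.08,
    "prev_ec_mild": 0.050,
    "prev_ec_mod": 0.015,
    "prev_ec_sev": 0.005,
    "prev_ec_early": 0.002,
    "prev_ec_adv": 0.0005,
    "prev_gc_lgin": 0.040,
    "prev_gc_hgin": 0.004,
    "prev_gc_early": 0.0015,
    "prev_gc_adv": 0.0005,
    "lt_level": 0.002,
    "lt_slope": 0.09,
}

_PROGRESSION_KEYS = ("tp_onset_ec", "tp_onset_gc", "tp_ec_mild_mod",
                     "tp_ec_mod_sev", "tp_ec_sev_early", "tp_ec_early_adv",
                     "tp_gc_lgin_hgin", "tp_gc_hgin_early",
                     "tp_gc_early_adv")
_PREVALENCE_KEYS = tuple(k for k in SYNTHETIC_DEFAULTS if
                         k.startswith("prev_"))


def _synthetic_distributions() -> dict[str, DistributionSpec]:
    dists = {}
    for name, base in SYNTHETIC_DEFAULTS.items():
        if name.startswith("lt_"):
            dists[name] = _fixed(base, 0.5 * base, 1.5 * base)
        elif name.startswith("surv5_"):
            lo, hi = 0.8 * base, min(1.0, 1.2 * base)
            dists[name] = _tri(lo, min(base, hi), hi)
        else:
            lo, hi = 0.5 * base, min(1.0, 1.5 * base)
            dists[name] = _tri(lo, base, hi)
    return dists


def default_groups() -> tuple[ParameterGroup, ...]:
    """One-way sweep groups, correlated members moving together."""
    return (
        ParameterGroup("utility_scores", (
            "utility_ec_mild", "utility_ec_mod", "utility_ec_sev",
            "utility_ec_early", "utility_ec_adv", "utility_gc_lgin",
            "utility_gc_hgin", "utility_gc_early", "utility_gc_adv")),
        ParameterGroup("compliance_screening", ("compliance_screening",)),
        ParameterGroup("discount_rate", ("discount_rate",)),
        ParameterGroup("prevalences", _PREVALENCE_KEYS),
        ParameterGroup("screening_costs", (
            "cost_mobilization", "cost_endoscopy", "cost_complication")),
        ParameterGroup("tp_ec_sev_early", ("tp_ec_sev_early",)),
    )


def _jittered(values: dict[str, float], seed: int | None,
              keys: tuple[str, ...]) -> dict[str, float]:
    if seed is None:
        return dict(values)
    rng = np.random.default_rng(seed)
    out = dict(values)
    for k in keys:
        out[k] = float(np.clip(out[k] * rng.uniform(0.9, 1.1), 0.0, 1.0))
    return out


def synthetic_values(config: SyntheticConfig | None = None
                     ) -> dict[str, float]:
    """Synthetic natural-history values after jitter and scaling."""
    config = config or SyntheticConfig()
    jitter_keys = tuple(k for k in SYNTHETIC_DEFAULTS
                        if k.startswith(("tp_", "prev_", "recur_")))
    vals = _jittered(SYNTHETIC_DEFAULTS, config.seed, jitter_keys)
    for k in _PROGRESSION_KEYS:
        vals[k] = min(1.0, vals[k] * config.progression_scale)
    for k in _PREVALENCE_KEYS:
        vals[k] = vals[k] * config.prevalence_scale
    vals["lt_level"], vals["lt_slope"] = config.life_table_params
    return vals


def build_transition_matrix(values: dict[str, float],
                            space: StateSpace) -> TransitionMatrix:
    """Assemble the annual natural-history matrix from named values.

    Structure: onset from normal into each organ's first precancer
    stage; stepwise progression along each chain with regression
    between adjacent precancer stages; detection status preserved under
    progression/regression; cancer mortality from survival-derived
    annual probabilities; recurrence from posttreatment back to the
    corresponding detected state.  Background mortality is overlaid
    per age by the engine, not stored here.
    """
    n = len(space)
    m = np.zeros((n, n))
    ix = space.idx
    v = values

    def set_row(row_id: str, moves: dict[str, float]) -> None:
        i = ix(row_id)
        total = 0.0
        for dest, p in moves.items():
            if p < 0:
                raise SyntheticError(f"negative probability for "
                                     f"{row_id} -> {dest}")
            m[i, ix(dest)] += p
            total += p
        if total > 1.0 + 1e-12:
            raise SyntheticError(
                f"row {row_id}: outgoing probability {total:.4f} > 1")
        m[i, i] += 1.0 - total

    mort = {
        "ec_early": annual_prob_from_survival(v["surv5_ec_early"]),
        "gc_early": annual_prob_from_survival(v["surv5_gc_early"]),
        "ec_adv": annual_prob_from_survival(v["surv5_ec_adv"]),
        "gc_adv": annual_prob_from_survival(v["surv5_gc_adv"]),
        "ec_adv_pt": annual_prob_from_survival(v["surv5_ec_adv_treated"]),
        "gc_adv_pt": annual_prob_from_survival(v["surv5_gc_adv_treated"]),
    }

    set_row("normal", {"ec_mild_u": v["tp_onset_ec"],
                       "gc_lgin_u": v["tp_onset_gc"]})
    for d in ("u", "d"):
        set_row(f"ec_mild_{d}", {f"ec_mod_{d}": v["tp_ec_mild_mod"],
                                 "normal": v["tp_ec_mild_reg"]})
        set_row(f"ec_mod_{d}", {f"ec_sev_{d}": v["tp_ec_mod_sev"],
                                f"ec_mild_{d}": v["tp_ec_mod_reg"]})
        set_row(f"ec_sev_{d}", {f"ec_early_{d}": v["tp_ec_sev_early"],
                                f"ec_mod_{d}": v["tp_ec_sev_reg"]})
        set_row(f"ec_early_{d}", {f"ec_adv_{d}": v["tp_ec_early_adv"],
                                  "death": mort["ec_early"]})
        set_row(f"ec_adv_{d}", {"death": mort["ec_adv"]})
        set_row(f"gc_lgin_{d}", {f"gc_hgin_{d}": v["tp_gc_lgin_hgin"],
                                 "normal": v["tp_gc_lgin_reg"]})
        set_row(f"gc_hgin_{d}", {f"gc_early_{d}": v["tp_gc_hgin_early"],
                                 f"gc_lgin_{d}": v["tp_gc_hgin_reg"]})
        set_row(f"gc_early_{d}", {f"gc_adv_{d}": v["tp_gc_early_adv"],
                                  "death": mort["gc_early"]})
        set_row(f"gc_adv_{d}", {"death": mort["gc_adv"]})
    set_row("ec_sev_pt", {"ec_sev_d": v["recur_precancer"]})
    set_row("gc_hgin_pt", {"gc_hgin_d": v["recur_precancer"]})
    set_row("ec_early_pt", {"ec_early_d": v["recur_early"],
                            "death": mort["ec_early"]})
    set_row("gc_early_pt", {"gc_early_d": v["recur_early"],
                            "death": mort["gc_early"]})
    set_row("ec_adv_pt", {"ec_adv_d": v["recur_adv"],
                          "death": mort["ec_adv_pt"]})
    set_row("gc_adv_pt", {"gc_adv_d": v["recur_adv"],
                          "death": mort["gc_adv_pt"]})
    m[space.death_index] = 0.0
    m[space.death_index, space.death_index] = 1.0

    matrix = TransitionMatrix(m, space.ids)
    report = validate_matrix(matrix, space)
    if not report:
        raise SyntheticError("generated matrix failed validation: " +
                             "; ".join(report.issues))
    return matrix


def synth_transition_matrix(seed: int | None = None,
                            config: SyntheticConfig | None = None,
                            space: StateSpace | None = None
                            ) -> TransitionMatrix:
    """Deterministic synthetic transition matrix for a given seed."""
    config = config or SyntheticConfig(seed=seed)
    if seed is not None and config.seed != seed:
        config = SyntheticConfig(seed, config.prevalence_scale,
                                 config.progression_scale,
                                 config.life_table_params)
    return build_transition_matrix(synthetic_values(config),
                                   space or build_state_space())


def prevalence_from_values(values: dict[str, float], space: StateSpace,
                           size: float) -> np.ndarray:
    """Baseline occupancy: all lesion mass undetected, rest normal."""
    occ = np.zeros(len(space))
    total = 0.0
    for key in _PREVALENCE_KEYS:
        state_id = key.replace("prev_", "") + "_u"
        p = values[key]
        if p < 0:
            raise SyntheticError(f"negative prevalence {key}")
        occ[space.idx(state_id)] = p * size
        total += p
    if total > 1.0:
        raise SyntheticError(f"prevalences sum to {total:.3f} > 1")
    occ[space.idx("normal")] = (1.0 - total) * size
    return occ


def synth_initial_prevalence(seed: int | None = None,
                             config: SyntheticConfig | None = None,
                             space: StateSpace | None = None,
                             size: float = 100_000) -> np.ndarray:
    config = config or SyntheticConfig(seed=seed)
    return prevalence_from_values(synthetic_values(config),
                                  space or build_state_space(), size)


def synth_life_table(params: tuple[float, float],
                     ages: range = range(40, 100)) -> pd.Series:
    """Gompertz-type background mortality: q(a) = 1 - exp(-l e^{s(a-40)}).

    ``params`` is (level, slope): the annual mortality hazard at age 40
    and its exponential increase per year of age.  Probabilities are
    strictly increasing in age and bounded in (0, 1).
    """
    level, slope = params
    if level <= 0 or slope <= 0:
        raise SyntheticError("life-table parameters must be positive")
    a = np.array(list(ages), dtype=float)
    q = 1.0 - np.exp(-level * np.exp(slope * (a - 40.0)))
    return pd.Series(q, index=list(ages), name="q_annual")


def default_parameter_set(config: SyntheticConfig | None = None
                          ) -> ParameterSet:
    """Full model parameterization: published base values + synthetic
    natural history, ready to drive every pipeline stage."""
    config = config or SyntheticConfig()
    values, dists = default_table1_params()
    values.update(synthetic_values(config))
    dists.update(_synthetic_distributions())
    return ParameterSet(values=values, distributions=dists,
                        groups=default_groups(),
                        source="table1_base_case+synthetic_natural_history")


def write_bundle(pset: ParameterSet, out_dir,
                 space: StateSpace | None = None) -> dict[str, Path]:
    """Write the parameter set as config + CSV matrices.

    Emits ``params.yaml`` (the schema the model consumes and that a
    user-supplied file can replace), the transition matrix and the
    life table.
    """
    space = space or build_state_space()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "params": out / "params.yaml",
        "matrix": out / "transition_matrix.csv",
        "life_table": out / "life_table.csv",
        "state_space": out / "state_space.yaml",
    }
    pset.to_yaml(paths["params"])
    build_transition_matrix(pset.values, space).to_csv(paths["matrix"])
    pset.life_table.rename_axis("age").to_csv(paths["life_table"])
    space.to_yaml(paths["state_space"])
    return paths
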