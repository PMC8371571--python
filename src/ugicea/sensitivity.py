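"""Univariate sensitivity sweeps and probabilistic sensitivity analysis.

Parameter uncertainty is described per parameter by a
:class:`DistributionSpec`: a fixed value, a triangular(min, mode, max),
a beta(shape1, shape2), or a gamma(shape, rate) distribution, together
with a (low, high) range used by one-way sweeps.  Parameters that move
together in the one-way analysis (e.g. the nine utility scores) are
collected in a :class:`ParameterGroup` and set to a common relative
position — both limits low or both high — realizing their positive
correlation.

The PSA samples all uncertain parameters jointly once per draw and
evaluates every strategy on that common draw (common random numbers),
yielding a per-draw (cost, QALY) matrix from which cost-effectiveness
acceptability curves and probability-optimal curves are computed via
net monetary benefit, NMB = WTP x QALYs - cost.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Runner = Callable[[Mapping[str, float]], Sequence[tuple[str, float, float]]]


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty description for one model parameter.

    ``params`` is (min, mode, max) for triangular, (shape1, shape2) for
    beta, (shape, rate) for gamma, and the single value for fixed.
    ``range`` is the (low, high) interval swept in one-way analyses;
    ``domain`` optionally clips sampled values to a semantic domain
    such as [0, 1] for probabilities.
    """

    kind: str
    params: tuple[float, ...]
    range: tuple[float, float] | None = None
    domain: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "triangular", "beta", "gamma"):
            raise SensitivityError(f"unknown distribution {self.kind!r}")
        if self.kind == "triangular":
            a, m, b = self.params
            if not a <= m <= b:
                raise SensitivityError(
                    f"triangular parameters out of order: {self.params}")
        elif self.kind in ("beta", "gamma"):
            if any(p <= 0 for p in self.params):
                raise SensitivityError(
                    f"{self.kind} shapes must be positive: {self.params}")
        if self.range is not None and self.range[0] > self.range[1]:
            raise SensitivityError(f"range out of order: {self.range}")

    @property
    def mean(self) -> float:
        if self.kind == "fixed":
            return self.params[0]
        if self.kind == "triangular":
            return sum(self.params) / 3.0
        if self.kind == "beta":
            a, b = self.params
            return a / (a + b)
        shape, rate = self.params
        return shape / rate

    def check_mean(self, base_value: float, tol: float = 0.10) -> None:
        """Verify a beta/gamma mean approximates the base-case value."""
        if self.kind not in ("beta", "gamma") or base_value == 0:
            return
        rel = abs(self.mean - base_value) / abs(base_value)
        if rel > tol:
            raise SensitivityError(
                f"{self.kind}{self.params} mean {self.mean:.4g} deviates "
                f"{rel:.1%} from base case {base_value:.4g}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            value = self.params[0]
        elif self.kind == "triangular":
            a, m, b = self.params
            value = m if a == b else float(rng.triangular(a, m, b))
        elif self.kind == "beta":
            value = float(rng.beta(*self.params))
        else:
            shape, rate = self.params
            value = float(rng.gamma(shape, 1.0 / rate))
        if self.domain is not None:
            value = min(max(value, self.domain[0]), self.domain[1])
        return value


def sample_parameter(spec: DistributionSpec,
                     rng: np.random.Generator) -> float:
    """One draw from a parameter's distribution (domain-clipped)."""
    return spec.sample(rng)


@dataclass(frozen=True)
class ParameterGroup:
    """Parameters swept simultaneously with positive correlation."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise SensitivityError(f"group {self.name!r} has no members")


@dataclass
class PSASampleSet:
    """Per-draw discounted (cost, QALY) pairs across strategies."""

    strategies: list[str]
    costs: np.ndarray   # (n, S)
    qalys: np.ndarray   # (n, S)
    seed: int
    n: int
    resampled_draws: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SensitivityError("need at least one PSA draw")
        if not (np.all(np.isfinite(self.costs)) and
                np.all(np.isfinite(self.qalys))):
            raise SensitivityError("non-finite PSA entries")


def one_way_sweep(group: ParameterGroup, runner: Runner,
                  ranges: Mapping[str, tuple[float, float]],
                  reference: str = "no_screening",
                  gdp_per_capita: float | None = None) -> pd.DataFrame:
    """Evaluate both limits of a parameter group and collect ICERs.

    All group members move together to their low limits, then to their
    high limits.  For every strategy the ICER versus the reference and
    versus the next most effective strategy is recorded at each limit,
    along with the per-comparison maximum ("upper limit") and its WHO
    GDP-multiple flag.  A model failure at a limit is recorded as
    missing with a diagnostic rather than aborting the sweep.
    """
    from .cea import (CEThresholds, compare_to_reference, frontier_sequence,
                      who_category)

    for m in group.members:
        if m not in ranges:
            raise SensitivityError(
                f"group member {m!r} has no sweep range")
    thresholds = CEThresholds(gdp_per_capita) if gdp_per_capita \
        else CEThresholds()

    results: dict[str, dict] = {}
    for side, limit in (("low", 0), ("high", 1)):
        overrides = {m: ranges[m][limit] for m in group.members}
        try:
            outcomes = list(runner(overrides))
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("model failed at %s limit of %s: %s",
                           side, group.name, exc)
            continue
        for cmp_kind, comps in (
                ("vs_reference", compare_to_reference(outcomes, reference)),
                ("vs_next", frontier_sequence(outcomes, "sequential"))):
            for c in comps:
                key = f"{c.strategy}|{cmp_kind}"
                row = results.setdefault(key, {
                    "group": group.name, "strategy": c.strategy,
                    "comparison": cmp_kind,
                    "icer_low": np.nan, "icer_high": np.nan})
                row[f"icer_{side}"] = np.nan if c.icer is None else c.icer
                row[f"flag_{side}"] = c.flag

    rows = []
    for row in results.values():
        both = [v for v in (row["icer_low"], row["icer_high"])
                if not (isinstance(v, float) and math.isnan(v))]
        upper = max(both) if both else np.nan
        row["upper_limit"] = upper
        row["gdp_flag"] = (who_category(upper, thresholds)
                           if both else "undefined")
        rows.append(row)
    return pd.DataFrame(rows)


def run_psa(param_specs: Mapping[str, DistributionSpec], runner: Runner,
            n_draws: int, seed: int, max_resamples: int = 100
            ) -> PSASampleSet:
    """Joint probabilistic sensitivity analysis.

    Per draw, every uncertain (non-fixed) parameter is sampled once and
    all strategies are evaluated on that common draw.  Draws producing
    an invalid model (e.g. a non-stochastic transition matrix) are
    resampled and counted.
    """
    if n_draws < 1:
        raise SensitivityError("n_draws must be at least 1")
    rng = np.random.default_rng(seed)
    uncertain = {k: s for k, s in param_specs.items() if s.kind != "fixed"}

    strategies: list[str] | None = None
    costs, qalys = [], []
    resampled = 0
    for _ in range(n_draws):
        for _attempt in range(max_resamples):
            overrides = {k: s.sample(rng) for k, s in uncertain.items()}
            try:
                outcomes = list(runner(overrides))
                break
            except Exception as exc:
                resampled += 1
                logger.debug("resampling invalid PSA draw: %s", exc)
        else:
            raise SensitivityError(
                f"PSA draw failed {max_resamples} times in a row")
        names = [o[0] for o in outcomes]
        if strategies is None:
            strategies = names
        elif names != strategies:
            raise SensitivityError("strategy order changed across draws")
        qalys.append([o[1] for o in outcomes])
        costs.append([o[2] for o in outcomes])
    if resampled:
        logger.info("PSA resampled %d invalid draws", resampled)
    return PSASampleSet(strategies=list(strategies),
                        costs=np.asarray(costs), qalys=np.asarray(qalys),
                        seed=seed, n=n_draws, resampled_draws=resampled)


def default_wtp_grid(gdp_per_capita: float = 10_276.0,
                     n_points: int = 100) -> np.ndarray:
    """Willingness-to-pay grid from 0 to three times per-capita GDP."""
    return np.linspace(0.0, 3.0 * gdp_per_capita, n_points)


def ceac_vs_comparator(samples: PSASampleSet, comparator: str,
                       wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Probability each strategy beats a comparator, per WTP.

    The probability at a willingness-to-pay w is the fraction of draws
    in which NMB(strategy) = w*QALYs - cost exceeds NMB(comparator).
    Long-format output: (strategy, wtp, probability).
    """
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise SensitivityError("empty willingness-to-pay grid")
    if comparator not in samples.strategies:
        raise SensitivityError(f"comparator {comparator!r} not in samples")
    c_idx = samples.strategies.index(comparator)
    rows = []
    for s_idx, name in enumerate(samples.strategies):
        if s_idx == c_idx:
            continue
        dq = samples.qalys[:, s_idx] - samples.qalys[:, c_idx]
        dc = samples.costs[:, s_idx] - samples.costs[:, c_idx]
        # NMB difference per (draw, wtp); probability over draws
        nmb_diff = np.outer(dq, wtp) - dc[:, None]
        prob = (nmb_diff > 0).mean(axis=0)
        rows.append(pd.DataFrame({"strategy": name, "wtp": wtp,
                                  "probability": prob}))
    return pd.concat(rows, ignore_index=True)


def prob_optimal(samples: PSASampleSet,
                 wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Probability each strategy maximizes NMB, per WTP (ties split).

    Probabilities across strategies sum to one at every
    willingness-to-pay point.
    """
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise SensitivityError("empty willingness-to-pay grid")
    if len(samples.strategies) < 1:
        raise SensitivityError("no strategies in sample set")
    rows = []
    probs = np.zeros((len(samples.strategies), wtp.size))
    for j, w in enumerate(wtp):
        nmb = w * samples.qalys - samples.costs  # (n, S)
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best)
        share = winners / winners.sum(axis=1, keepdims=True)
        probs[:, j] = share.mean(axis=0)
    for s_idx, name in enumerate(samples.strategies):
        rows.append(pd.DataFrame({"strategy": name, "wtp": wtp,
                                  "probability": probs[s_idx]}))
    return pd.concat(rows, ignore_index=True)
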