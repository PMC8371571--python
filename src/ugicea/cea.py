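"""Incremental cost-effectiveness analysis.

Two comparison modes are provided.  The default ``sequential`` mode
orders strategies by effectiveness and compares each with its
predecessor without removing dominated or extendedly dominated options
(so the resulting ICER sequence need not be monotone).  The
``frontier`` mode applies the standard efficient-frontier algorithm:
strictly dominated strategies are dropped, then strategies whose ICER
exceeds that of a more effective alternative (extended dominance) are
iteratively removed, leaving strictly increasing ICERs.

ICERs are classified against WHO GDP-multiple willingness-to-pay
thresholds: below one times per-capita GDP is highly cost-effective,
one to three times is cost-effective, above three times is not
cost-effective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

DEFAULT_GDP_PER_CAPITA = 10_276.0  # China, 2019 US$

HIGHLY_COST_EFFECTIVE = "highly cost-effective"
COST_EFFECTIVE = "cost-effective"
NOT_COST_EFFECTIVE = "not cost-effective"

DOMINANT = "dominant"
DOMINATED = "dominated"
EQUIVALENT = "equivalent"


class CEAError(ValueError):
    pass


@dataclass(frozen=True)
class CEThresholds:
    gdp_per_capita: float = DEFAULT_GDP_PER_CAPITA

    def __post_init__(self) -> None:
        if self.gdp_per_capita <= 0:
            raise CEAError("GDP per capita must be positive")


@dataclass(frozen=True)
class Comparison:
    """One pairwise incremental comparison."""

    strategy: str
    comparator: str
    incremental_qalys: float
    incremental_cost: float
    icer: float | None          # $/QALY, None when flagged
    flag: str | None = None     # dominant / dominated / equivalent / tie

    @property
    def icer_rounded(self) -> int | None:
        return None if self.icer is None else round_dollars(self.icer)


def round_dollars(x: float) -> int:
    """Round to whole dollars, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def icer(incremental_cost: float, incremental_qalys: float
         ) -> float | str:
    """ICER in $/QALY, or a dominance flag when the ratio is undefined.

    A strategy that gains QALYs at no extra (or negative) cost is
    ``dominant``; one that loses QALYs at extra cost is ``dominated``;
    zero increments on both axes are ``equivalent``.
    """
    if incremental_qalys == 0 and incremental_cost == 0:
        return EQUIVALENT
    if incremental_qalys > 0:
        return incremental_cost / incremental_qalys
    if incremental_cost >= 0:
        return DOMINATED
    # fewer QALYs but cheaper: a genuine (south-west) trade-off; report
    # the signed ratio so the caller can judge it against a threshold
    return incremental_cost / incremental_qalys


def _compare(strategy, comparator) -> Comparison:
    dq = strategy[1] - comparator[1]
    dc = strategy[2] - comparator[2]
    val = icer(dc, dq)
    if isinstance(val, str):
        return Comparison(strategy[0], comparator[0], dq, dc, None, val)
    return Comparison(strategy[0], comparator[0], dq, dc, val)


def compare_to_reference(outcomes: Sequence[tuple[str, float, float]],
                         reference: str) -> list[Comparison]:
    """Compare every strategy with a named reference (e.g. no screening)."""
    by_name = {o[0]: o for o in outcomes}
    if reference not in by_name:
        raise CEAError(f"reference strategy {reference!r} not in outcomes")
    ref = by_name[reference]
    return [_compare(o, ref) for o in outcomes if o[0] != reference]


def frontier_sequence(outcomes: Sequence[tuple[str, float, float]],
                      mode: str = "sequential") -> list[Comparison]:
    """Incremental comparisons versus the next most effective strategy.

    ``outcomes`` are (name, qalys, cost) tuples; input order is
    irrelevant.  In ``sequential`` mode every strategy (from the second
    in effectiveness order) is compared with its predecessor.  In
    ``frontier`` mode dominated and extendedly dominated strategies are
    removed first, so surviving ICERs increase with effectiveness.
    """
    if len(outcomes) < 2:
        raise CEAError("need at least two strategies to compare")
    if mode not in ("sequential", "frontier"):
        raise CEAError(f"unknown comparison mode {mode!r}")
    ordered = sorted(outcomes, key=lambda o: (o[1], o[2]))

    if mode == "sequential":
        out = []
        for prev, cur in zip(ordered, ordered[1:]):
            cmp = _compare(cur, prev)
            if cmp.incremental_qalys == 0:
                cmp = Comparison(cmp.strategy, cmp.comparator, 0.0,
                                 cmp.incremental_cost, None, "tie")
            out.append(cmp)
        return out

    # frontier mode: drop strictly dominated (costlier, no more QALYs)
    kept = list(ordered)
    kept = [o for o in kept
            if not any(other[1] >= o[1] and other[2] < o[2] or
                       other[1] > o[1] and other[2] <= o[2]
                       for other in kept)]
    # iteratively enforce increasing ICERs (extended dominance)
    while True:
        comps = [_compare(cur, prev) for prev, cur in zip(kept, kept[1:])]
        ratios = [c.icer if c.icer is not None else math.inf for c in comps]
        removed = False
        for i in range(len(ratios) - 1):
            if ratios[i] > ratios[i + 1]:
                del kept[i + 1]  # the strategy with the higher ICER
                removed = True
                break
        if not removed:
            return comps


def who_category(icer_value: float,
                 thresholds: CEThresholds = CEThresholds()) -> str:
    """Three-way WHO classification of an ICER against GDP multiples."""
    if not math.isfinite(icer_value):
        raise CEAError("ICER must be finite")
    gdp = thresholds.gdp_per_capita
    if icer_value < gdp:
        return HIGHLY_COST_EFFECTIVE
    if icer_value <= 3.0 * gdp:
        return COST_EFFECTIVE
    return NOT_COST_EFFECTIVE
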