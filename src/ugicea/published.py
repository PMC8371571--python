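"""Published base-case results table, shipped as packaged data.

The base-case table reports, for each initial screening age band and
strategy, total discounted QALYs and cost (in thousands of 2019 US$)
for a 100 000-person cohort, together with the printed incremental
columns and ICERs versus no screening and versus the next most
effective strategy.  It serves as the reference input for ICER
arithmetic checks and frontier recomputation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

AGE_BANDS = ("40-44", "45-49", "50-54", "55-59", "60-64", "65-69")


def load_published_basecase() -> pd.DataFrame:
    """Base-case results per (age band, strategy), costs in $thousand."""
    ref = resources.files("ugicea").joinpath("data/basecase_published.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def block_outcomes(frame: pd.DataFrame, age_band: str
                   ) -> list[tuple[str, float, float]]:
    """(strategy, QALYs, cost in $) tuples for one age block."""
    block = frame[frame["age_band"] == age_band]
    if block.empty:
        raise KeyError(f"no rows for age band {age_band!r}")
    return [(r.strategy, float(r.qalys), float(r.cost_thousand) * 1000.0)
            for r in block.itertuples()]
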