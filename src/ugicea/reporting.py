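"""Publication-style result tables.

The base-case layout mirrors the conventional presentation: one row per
(initial age band, strategy) with QALYs, incremental QALYs versus no
screening and versus the next most effective strategy, costs in
thousands of dollars, the matching incremental costs, and ICERs rounded
to whole dollars.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import compare_to_reference, frontier_sequence

BASECASE_COLUMNS = (
    "age_band", "strategy", "qalys",
    "inc_qalys_vs_none", "inc_qalys_vs_next",
    "cost_thousand", "inc_cost_vs_none_thousand",
    "inc_cost_vs_next_thousand", "icer_vs_none", "icer_vs_next")


def basecase_table(outcomes_by_age: Mapping[
        str, Sequence[tuple[str, float, float]]],
        reference: str = "no_screening") -> pd.DataFrame:
    """Assemble the nine-column base-case table across age bands."""
    rows = []
    for age_band, outcomes in outcomes_by_age.items():
        vs_none = {c.strategy: c
                   for c in compare_to_reference(outcomes, reference)}
        vs_next = {c.strategy: c
                   for c in frontier_sequence(outcomes, "sequential")}
        ordered = sorted(outcomes, key=lambda o: o[1])
        for name, qalys, cost in ordered:
            n = vs_none.get(name)
            x = vs_next.get(name)
            rows.append({
                "age_band": age_band, "strategy": name,
                "qalys": qalys,
                "inc_qalys_vs_none":
                    n.incremental_qalys if n else np.nan,
                "inc_qalys_vs_next":
                    x.incremental_qalys if x else np.nan,
                "cost_thousand": cost / 1000.0,
                "inc_cost_vs_none_thousand":
                    n.incremental_cost / 1000.0 if n else np.nan,
                "inc_cost_vs_next_thousand":
                    x.incremental_cost / 1000.0 if x else np.nan,
                "icer_vs_none":
                    n.icer_rounded if n and n.icer is not None else np.nan,
                "icer_vs_next":
                    x.icer_rounded if x and x.icer is not None else np.nan,
            })
    return pd.DataFrame(rows, columns=list(BASECASE_COLUMNS))


def write_csv_with_metadata(frame: pd.DataFrame, path,
                            metadata: Mapping[str, str]) -> None:
    """CSV with ``# key: value`` provenance header lines."""
    with open(path, "w") as fh:
        for key, value in metadata.items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False)


def read_csv_with_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
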