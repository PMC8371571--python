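#!/usr/bin/env python
"""Generate the full model parameter bundle.

Assembles the published base-case estimates (compliance, test
characteristics, costs, utilities, discount rate, with their ranges and
uncertainty distributions) together with the synthetic natural-history
stand-ins (transition matrix, baseline prevalences, background life
table) and writes the bundle the remaining analyses consume.

Output: results/parameters/{params.yaml, transition_matrix.csv,
life_table.csv, state_space.yaml}
"""

from pathlib import Path

from ugicea.state_space import build_state_space, validate_matrix
from ugicea.synthetic import (build_transition_matrix,
                              default_parameter_set, write_bundle)

OUT = Path(__file__).resolve().parents[1] / "results" / "parameters"


def main() -> None:
    pset = default_parameter_set()
    paths = write_bundle(pset, OUT)
    space = build_state_space()
    matrix = build_transition_matrix(pset.values, space)
    report = validate_matrix(matrix, space)
    print(f"parameter source: {pset.source}")
    print(f"parameters: {len(pset.values)} named values, "
          f"{sum(1 for s in pset.distributions.values() if s.kind != 'fixed')} "
          f"uncertain")
    print(f"state space: {len(space)} states "
          f"(partition {space.partition_sizes()})")
    print(f"transition matrix valid: {bool(report)}")
    for name, path in paths.items():
        print(f"wrote {name}: {path}")


if __name__ == "__main__":
    main()
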