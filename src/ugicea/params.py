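"""A single validated container for every model input.

A :class:`ParameterSet` holds a flat ``values`` mapping (named base-case
values for screening characteristics, compliance, costs, utilities,
transition probabilities, prevalences and the life-table shape), the
per-parameter uncertainty :class:`~ugicea.sensitivity.DistributionSpec`
objects, the correlated one-way sweep groups, and the background life
table.  Everything downstream — the transition matrix, the screening
and economic parameter objects, the initial prevalence vector — is
built from it, so overriding named values (for sweeps or PSA draws)
re-parameterizes the whole model consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import pandas as pd
import yaml

from .sensitivity import DistributionSpec, ParameterGroup, SensitivityError
from .strategies import ScreeningParams


class ParameterError(ValueError):
    pass


@dataclass
class ParameterSet:
    values: dict[str, float]
    distributions: dict[str, DistributionSpec]
    groups: tuple[ParameterGroup, ...] = ()
    life_table_override: pd.Series | None = None
    source: str = "unspecified"
    #: distribution means are checked against base-case values when a
    #: base set is constructed or loaded; derived sets (parameter
    #: overrides from sweeps or PSA draws) skip the check since their
    #: values deliberately deviate from the distribution means
    validate_distributions: bool = True

    def __post_init__(self) -> None:
        for name, spec in self.distributions.items():
            if name not in self.values:
                raise ParameterError(
                    f"distribution for unknown parameter {name!r}")
            if not self.validate_distributions:
                continue
            try:
                spec.check_mean(self.values[name])
            except SensitivityError as exc:
                raise ParameterError(str(exc)) from exc
        member_seen: set[str] = set()
        for g in self.groups:
            overlap = member_seen & set(g.members)
            if overlap:
                raise ParameterError(
                    f"parameters {sorted(overlap)} appear in more than "
                    "one group")
            member_seen |= set(g.members)

    # -- derived model inputs ---------------------------------------------
    def with_values(self, overrides: Mapping[str, float]) -> "ParameterSet":
        unknown = set(overrides) - set(self.values)
        if unknown:
            raise ParameterError(f"unknown parameters {sorted(unknown)}")
        merged = dict(self.values)
        merged.update(overrides)
        return replace(self, values=merged, validate_distributions=False)

    @property
    def life_table(self) -> pd.Series:
        if self.life_table_override is not None:
            return self.life_table_override
        from .synthetic import synth_life_table
        return synth_life_table((self.values["lt_level"],
                                 self.values["lt_slope"]))

    @property
    def discount_rate(self) -> float:
        return self.values["discount_rate"]

    def screening_params(self) -> ScreeningParams:
        v = self.values
        return ScreeningParams(
            compliance_screening=v["compliance_screening"],
            compliance_reexamination=v["compliance_reexamination"],
            sens_ec=v["sens_ec"], spec_ec=v["spec_ec"],
            sens_gc=v["sens_gc"], spec_gc=v["spec_gc"],
            complication_rate=v["complication_rate"],
            self_exam_probs={
                "severe": v["selfexam_severe"],
                "early": v["selfexam_early"],
                "advanced": v["selfexam_advanced"],
            },
            treatment_compliance={
                k: v[f"treat_compliance_{k}"]
                for k in ("ec_sev", "ec_early", "ec_adv",
                          "gc_hgin", "gc_early", "gc_adv")},
            fp_disutility=v["fp_disutility"],
        )

    def sweep_ranges(self) -> dict[str, tuple[float, float]]:
        return {name: spec.range
                for name, spec in self.distributions.items()
                if spec.range is not None}

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "source": self.source,
            "values": {k: float(v) for k, v in self.values.items()},
            "distributions": {
                k: {"kind": s.kind, "params": list(s.params),
                    "range": list(s.range) if s.range else None,
                    "domain": list(s.domain) if s.domain else None}
                for k, s in self.distributions.items()},
            "groups": [{"name": g.name, "members": list(g.members)}
                       for g in self.groups],
        }
        if self.life_table_override is not None:
            payload["life_table"] = {
                int(a): float(q)
                for a, q in self.life_table_override.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        dists = {
            k: DistributionSpec(
                kind=d["kind"], params=tuple(d["params"]),
                range=tuple(d["range"]) if d.get("range") else None,
                domain=tuple(d["domain"]) if d.get("domain") else None)
            for k, d in payload.get("distributions", {}).items()}
        groups = tuple(ParameterGroup(g["name"], tuple(g["members"]))
                       for g in payload.get("groups", []))
        life = payload.get("life_table")
        life_series = None
        if life:
            life_series = pd.Series({int(a): float(q)
                                     for a, q in life.items()}).sort_index()
        return cls(values=dict(payload["values"]), distributions=dists,
                   groups=groups, life_table_override=life_series,
                   source=payload.get("source", "user_file"))
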