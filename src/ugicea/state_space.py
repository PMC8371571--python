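"""Health-state graph for esophageal and gastric cancer progression.

The model follows a closed cohort through mutually exclusive health
states.  Each organ has a precancerous chain (esophagus: mild dysplasia →
moderate dysplasia → severe dysplasia/CIS; stomach: LGIN → HGIN/CIS)
followed by early and advanced cancer.  Every lesion/cancer stage exists
in an *undetected* and a *detected* variant, and the stages that can be
treated endoscopically or surgically (severe dysplasia/CIS, HGIN/CIS,
early cancer, advanced cancer) additionally have a *posttreatment* state.
With the shared ``normal`` and ``death`` states the default space has

    2 + 9 stages x 2 detection flags + 6 posttreatment = 26 states.

Dual-primary lesions (simultaneous esophageal and gastric disease in one
person) are not represented: a cohort-level Markov model needs exclusive
states and dual-primary upper-GI cancer is rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

ORGANS = ("none", "esophagus", "stomach")
STAGES = (
    "normal",
    "mild_dysplasia",
    "moderate_dysplasia",
    "severe_dysplasia_cis",
    "lgin",
    "hgin_cis",
    "early_cancer",
    "advanced_cancer",
    "death",
)
DETECTIONS = ("undetected", "detected", "not_applicable")
TREATMENTS = ("untreated", "posttreatment", "not_applicable")

#: progression chains per organ, in stage order (precancer first)
EC_CHAIN = ("mild_dysplasia", "moderate_dysplasia", "severe_dysplasia_cis",
            "early_cancer", "advanced_cancer")
GC_CHAIN = ("lgin", "hgin_cis", "early_cancer", "advanced_cancer")

#: stages with an endoscopic/surgical treatment pathway (per organ)
DEFAULT_TREATABLE = ("severe_dysplasia_cis", "hgin_cis", "early_cancer",
                     "advanced_cancer")

#: stages kept under endoscopic surveillance when found at screening,
#: rather than treated immediately
LOW_GRADE_STAGES = ("mild_dysplasia", "moderate_dysplasia", "lgin")

_STAGE_ABBREV = {
    "mild_dysplasia": "mild",
    "moderate_dysplasia": "mod",
    "severe_dysplasia_cis": "sev",
    "lgin": "lgin",
    "hgin_cis": "hgin",
    "early_cancer": "early",
    "advanced_cancer": "adv",
}
_ORGAN_ABBREV = {"esophagus": "ec", "stomach": "gc"}


class StateSpaceError(ValueError):
    """Structural problem while building or aligning a state space."""


@dataclass(frozen=True)
class HealthState:
    """One mutually exclusive health state of the cohort model."""

    id: str
    organ: str
    stage: str
    detection: str
    treatment: str

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise StateSpaceError(f"unknown organ {self.organ!r}")
        if self.stage not in STAGES:
            raise StateSpaceError(f"unknown stage {self.stage!r}")
        if self.detection not in DETECTIONS:
            raise StateSpaceError(f"unknown detection {self.detection!r}")
        if self.treatment not in TREATMENTS:
            raise StateSpaceError(f"unknown treatment {self.treatment!r}")
        if self.stage in ("normal", "death"):
            if self.organ != "none" or self.detection != "not_applicable" \
                    or self.treatment != "not_applicable":
                raise StateSpaceError(
                    f"{self.stage} must have organ=none and "
                    "not_applicable detection/treatment flags")
        else:
            if self.organ == "none":
                raise StateSpaceError(
                    f"lesion state {self.id} needs an organ")
            if self.treatment == "posttreatment":
                if self.detection != "not_applicable":
                    raise StateSpaceError(
                        "posttreatment states carry no detection flag")
            elif self.detection not in ("undetected", "detected"):
                raise StateSpaceError(
                    f"lesion state {self.id} needs a detection flag")

    @property
    def is_living(self) -> bool:
        return self.stage != "death"


@dataclass(frozen=True)
class StateSpaceConfig:
    """Options controlling which chains and tiers are generated."""

    include_esophagus: bool = True
    include_stomach: bool = True
    treatable_stages: tuple[str, ...] = DEFAULT_TREATABLE

    def __post_init__(self) -> None:
        for st in self.treatable_stages:
            if st not in DEFAULT_TREATABLE:
                raise StateSpaceError(
                    f"posttreatment requested for non-treatable stage {st!r}")


@dataclass
class StateSpace:
    """Ordered collection of :class:`HealthState` with index helpers."""

    states: list[HealthState]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.states]
        if len(set(ids)) != len(ids):
            raise StateSpaceError("duplicate state ids")
        n_death = sum(s.stage == "death" for s in self.states)
        if n_death != 1:
            raise StateSpaceError(f"expected exactly one death state, "
                                  f"found {n_death}")
        self.index = {sid: i for i, sid in enumerate(ids)}

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.states]

    def idx(self, state_id: str) -> int:
        try:
            return self.index[state_id]
        except KeyError:
            raise StateSpaceError(f"unknown state id {state_id!r}") from None

    @property
    def death_index(self) -> int:
        return next(i for i, s in enumerate(self.states)
                    if s.stage == "death")

    @property
    def living_mask(self) -> np.ndarray:
        return np.array([s.is_living for s in self.states])

    # -- structured views used by the event operators ----------------------
    def detection_pairs(self) -> list[tuple[int, int, HealthState]]:
        """(undetected index, detected index, undetected state) triples."""
        out = []
        for s in self.states:
            if s.detection == "undetected":
                partner = s.id[:-2] + "_d"
                out.append((self.idx(s.id), self.idx(partner), s))
        return out

    def surveillance_indices(self) -> list[int]:
        """Detected low-grade lesion states (under annual reexamination)."""
        return [i for i, s in enumerate(self.states)
                if s.detection == "detected" and s.stage in LOW_GRADE_STAGES]

    def treatable_detected(self) -> dict[int, tuple[int, str]]:
        """Map detected-treatable index -> (posttreatment index, stage key)."""
        out = {}
        pt_index = {(s.organ, s.stage): i for i, s in enumerate(self.states)
                    if s.treatment == "posttreatment"}
        for i, s in enumerate(self.states):
            if s.detection == "detected" and (s.organ, s.stage) in pt_index:
                key = stage_key(s.organ, s.stage)
                out[i] = (pt_index[(s.organ, s.stage)], key)
        return out

    def undetected_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.states)
                if s.detection == "undetected"]

    def partition_sizes(self) -> tuple[int, int, int]:
        """(shared, detection-flagged lesion, posttreatment) state counts."""
        shared = sum(s.stage in ("normal", "death") for s in self.states)
        pt = sum(s.treatment == "posttreatment" for s in self.states)
        return shared, len(self.states) - shared - pt, pt

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = [{"id": s.id, "organ": s.organ, "stage": s.stage,
                    "detection": s.detection, "treatment": s.treatment}
                   for s in self.states]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StateSpace":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls([HealthState(**row) for row in payload])


def stage_key(organ: str, stage: str) -> str:
    """Short key like ``ec_early`` naming an (organ, stage) pair."""
    return f"{_ORGAN_ABBREV[organ]}_{_STAGE_ABBREV[stage]}"


def build_state_space(config: StateSpaceConfig | None = None) -> StateSpace:
    """Construct the canonical ordered state space.

    Default configuration yields the full 26-state space: normal, the
    esophageal chain (5 stages) and gastric chain (4 stages) each split
    into undetected/detected, one posttreatment state per treatable
    stage per organ, and death.
    """
    config = config or StateSpaceConfig()
    states: list[HealthState] = [
        HealthState("normal", "none", "normal",
                    "not_applicable", "not_applicable")]
    chains: list[tuple[str, tuple[str, ...]]] = []
    if config.include_esophagus:
        chains.append(("esophagus", EC_CHAIN))
    if config.include_stomach:
        chains.append(("stomach", GC_CHAIN))
    for organ, chain in chains:
        for stage in chain:
            base = stage_key(organ, stage)
            states.append(HealthState(f"{base}_u", organ, stage,
                                      "undetected", "untreated"))
            states.append(HealthState(f"{base}_d", organ, stage,
                                      "detected", "untreated"))
    for organ, chain in chains:
        for stage in chain:
            if stage in config.treatable_stages:
                base = stage_key(organ, stage)
                states.append(HealthState(f"{base}_pt", organ, stage,
                                          "not_applicable", "posttreatment"))
    states.append(HealthState("death", "none", "death",
                              "not_applicable", "not_applicable"))
    return StateSpace(states)


@dataclass
class TransitionMatrix:
    """Annual transition probabilities aligned to a state space order.

    ``values[i, j]`` is the probability of moving from state ``i`` to
    state ``j`` in one cycle, before any age-specific background
    mortality overlay.  ``age_dependence`` optionally maps an age to a
    full replacement matrix.
    """

    values: np.ndarray
    state_ids: list[str]
    age_dependence: Mapping[int, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or \
                self.values.shape[0] != self.values.shape[1]:
            raise StateSpaceError("transition matrix must be square")
        if self.values.shape[0] != len(self.state_ids):
            raise StateSpaceError("matrix size does not match state ids")

    def at_age(self, age: int) -> np.ndarray:
        if self.age_dependence and age in self.age_dependence:
            return np.asarray(self.age_dependence[age], dtype=float)
        return self.values

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.state_ids,
                     columns=self.state_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "TransitionMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(dtype=float), list(frame.index))


@dataclass
class MatrixValidationReport:
    ok: bool
    issues: list[str] = field(default_factory=list)
    offending_rows: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def validate_matrix(matrix: TransitionMatrix, space: StateSpace,
                    atol: float = 1e-9) -> MatrixValidationReport:
    """Check a transition matrix against the state-space contract.

    Passes iff the matrix is aligned to the space, row-stochastic and
    non-negative, death is absorbing, and no detected or posttreatment
    state ever transitions back to an undetected state (detection is
    irreversible).
    """
    if matrix.state_ids != space.ids:
        raise StateSpaceError(
            "matrix state ids are not aligned to the state space")
    issues: list[str] = []
    bad_rows: set[str] = set()
    vals = matrix.values
    if np.any(vals < -atol) or np.any(vals > 1 + atol):
        for i in np.unique(np.where((vals < -atol) | (vals > 1 + atol))[0]):
            issues.append(f"row {space.ids[i]}: entries outside [0, 1]")
            bad_rows.add(space.ids[i])
    sums = vals.sum(axis=1)
    for i in np.where(np.abs(sums - 1.0) > atol)[0]:
        issues.append(f"row {space.ids[i]}: sums to {sums[i]:.6g}")
        bad_rows.add(space.ids[i])
    d = space.death_index
    death_row = np.zeros(len(space))
    death_row[d] = 1.0
    if not np.allclose(vals[d], death_row, atol=atol):
        issues.append("death row is not absorbing")
        bad_rows.add("death")
    undetected = [i for i, s in enumerate(space.states)
                  if s.detection == "undetected"]
    for i, s in enumerate(space.states):
        if s.detection == "detected" or s.treatment == "posttreatment":
            if np.any(vals[i, undetected] > atol):
                issues.append(
                    f"row {s.id}: transition back to an undetected state")
                bad_rows.add(s.id)
    return MatrixValidationReport(not issues, issues, sorted(bad_rows))
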