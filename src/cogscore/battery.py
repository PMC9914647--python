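"""Battery definition and elementary scoring rules.

The screening battery modelled here comprises 14 sub-scores: six baseline
cognitive-control tasks (working-memory capacity/updating, attentional
control, inhibition + task/rule switching with separate switch-error and
failed-set counts, cognitive flexibility) whose internal scoring is treated
as opaque numerics, and the revised digital tasks with explicit scoring
rules — three cognitive-flexibility conditions rated as erroneous sets out
of 8, a visual-fluency condition counting distinct orderings of 4 pads
(24 possible), and two episodic-memory window-recognition conditions rated
as errors out of 15.

Every sub-score carries an orientation (whether higher raw values mean
better or worse cognition); :func:`orient_score` reflects higher-worse
scores so that, after orientation, "near the top of the range" always means
the cognitively better performance. Orientation must precede min–max
normalization downstream.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Sequence


class SubtaskKind(str, Enum):
    ERROR_COUNT = "error_count"
    CORRECT_COUNT = "correct_count"
    PERFORMANCE_SCORE = "performance_score"


class Orientation(str, Enum):
    HIGHER_BETTER = "higher_better"
    HIGHER_WORSE = "higher_worse"


class BatteryError(ValueError):
    """Domain error raised by battery scoring operations."""


@dataclass(frozen=True)
class SubtaskSpec:
    """Registry entry for one sub-score.

    ``min_score``/``max_score`` are ``None`` for unbounded (opaque baseline)
    scores. ``orientation`` is ``higher_worse`` exactly when the sub-score
    counts errors.
    """

    id: str
    label: str
    kind: SubtaskKind
    min_score: float | None
    max_score: float | None
    orientation: Orientation
    aliases: tuple[str, ...] = field(default=())

    @property
    def bounded(self) -> bool:
        return self.min_score is not None and self.max_score is not None

    def __post_init__(self) -> None:
        if self.bounded and not self.min_score < self.max_score:  # type: ignore[operator]
            raise BatteryError(f"{self.id}: min_score must be < max_score")
        if (self.kind is SubtaskKind.ERROR_COUNT) != (
            self.orientation is Orientation.HIGHER_WORSE
        ):
            raise BatteryError(
                f"{self.id}: orientation must be higher_worse iff kind is error_count"
            )

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "label": self.label,
            "kind": self.kind.value,
            "min_score": self.min_score,
            "max_score": self.max_score,
            "orientation": self.orientation.value,
            "aliases": list(self.aliases),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubtaskSpec":
        return cls(
            id=d["id"],
            label=d["label"],
            kind=SubtaskKind(d["kind"]),
            min_score=d["min_score"],
            max_score=d["max_score"],
            orientation=Orientation(d["orientation"]),
            aliases=tuple(d.get("aliases", ())),
        )


def load_battery(source) -> tuple[SubtaskSpec, ...]:
    """Load a registry from a JSON document (path, file object or dict)."""
    if hasattr(source, "read"):
        doc = json.load(source)
    elif isinstance(source, dict):
        doc = source
    else:
        with open(source) as fh:
            doc = json.load(fh)
    specs = tuple(SubtaskSpec.from_dict(d) for d in doc["subtasks"])
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise BatteryError("duplicate subtask ids in registry")
    return specs


def dump_battery(specs: Iterable[SubtaskSpec]) -> dict:
    return {"subtasks": [s.to_dict() for s in specs]}


def default_battery() -> tuple[SubtaskSpec, ...]:
    """The 14-entry default registry, in the battery's canonical task order."""
    ref = resources.files("cogscore.data").joinpath("battery.json")
    with ref.open() as fh:
        return load_battery(fh)


def battery_index(specs: Iterable[SubtaskSpec] | None = None) -> dict[str, SubtaskSpec]:
    """Mapping id -> spec (aliases included) for a registry."""
    specs = default_battery() if specs is None else tuple(specs)
    idx: dict[str, SubtaskSpec] = {}
    for s in specs:
        idx[s.id] = s
        for a in s.aliases:
            idx.setdefault(a, s)
    return idx


def enumerate_pad_orderings(n_pads: int) -> list[tuple[int, ...]]:
    """All distinct deactivation orders of pads 1..n_pads.

    The visual-fluency condition asks the examinee to find as many distinct
    orderings of the presented pads as possible; with 4 pads there are
    4! = 24. Guarded to n_pads <= 8 against factorial blow-up.
    """
    if not isinstance(n_pads, int) or isinstance(n_pads, bool):
        raise BatteryError("n_pads must be an integer")
    if not 1 <= n_pads <= 8:
        raise BatteryError(f"n_pads must be in [1, 8], got {n_pads}")
    return list(itertools.permutations(range(1, n_pads + 1)))


def score_recognition_errors(n_items: int, responses: Sequence[str]) -> int:
    """Number of incorrect recognitions among ``n_items`` probes.

    Each response is ``"correct"`` or ``"incorrect"``; the window-recognition
    conditions use n_items = 15, so the worst score is 15 errors.
    """
    if len(responses) != n_items:
        raise BatteryError(
            f"expected {n_items} responses, got {len(responses)}"
        )
    bad = set(responses) - {"correct", "incorrect"}
    if bad:
        raise BatteryError(f"invalid responses: {sorted(bad)}")
    return sum(1 for r in responses if r == "incorrect")


def score_set_errors(n_sets: int, set_outcomes: Sequence[str]) -> int:
    """Number of erroneous sets among ``n_sets``.

    Each outcome is ``"clean"`` or ``"erroneous"``; the flexibility
    conditions use n_sets = 8, so the worst score is 8 errors.
    """
    if len(set_outcomes) != n_sets:
        raise BatteryError(
            f"expected {n_sets} set outcomes, got {len(set_outcomes)}"
        )
    bad = set(set_outcomes) - {"clean", "erroneous"}
    if bad:
        raise BatteryError(f"invalid set outcomes: {sorted(bad)}")
    return sum(1 for o in set_outcomes if o == "erroneous")


def orient_score(spec: SubtaskSpec, raw: float) -> float:
    """Map a raw score so that higher oriented values mean better cognition.

    Higher-better scores pass through unchanged. Higher-worse scores are
    reflected: ``max_score - raw`` when bounded (keeping the oriented value
    inside the documented range) and ``-raw`` when unbounded. Reflection
    rather than plain negation keeps bounded oriented scores interpretable;
    min–max normalization downstream is affine-invariant, so the two choices
    are numerically equivalent after normalization.
    """
    if spec.bounded and not (spec.min_score <= raw <= spec.max_score):  # type: ignore[operator]
        raise BatteryError(
            f"{spec.id}: raw score {raw} outside bounds "
            f"[{spec.min_score}, {spec.max_score}]"
        )
    if spec.orientation is Orientation.HIGHER_BETTER:
        return raw
    if spec.bounded:
        return spec.max_score - raw  # type: ignore[operator]
    return -raw
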