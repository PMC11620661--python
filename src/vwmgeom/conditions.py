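"""Condition labels for the two visual-working-memory experiments.

Both experiments use 4 object types and 16 trial conditions per run:

* Experiment 1 — a single memory target held over a distractor-filled or
  blank delay: 12 target x distractor combinations (distractor differs
  from the target) plus 4 no-distractor conditions.
* Experiment 2 — two sequentially presented memory targets: 12 ordered
  pairs of distinct objects plus 4 single-target conditions (the singles
  are not analysed for target decoding).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Optional

OBJECTS = (1, 2, 3, 4)

EXP1 = "exp1"
EXP2 = "exp2"
EXPERIMENTS = (EXP1, EXP2)

#: order tags for Experiment 2 ordered-pair conditions
TARGET_FIRST = "target-first"
TARGET_SECOND = "target-second"
ORDER_NA = "n/a"


@dataclass(frozen=True)
class ConditionLabel:
    """One of the 16 trial conditions of an experiment.

    ``target`` is the memory target (Experiment 2: the first-shown
    target). ``context`` is the distractor identity (Experiment 1) or
    the partner-target identity (Experiment 2); ``None`` marks
    no-distractor / single-target conditions.
    """

    experiment: str
    target: int
    context: Optional[int] = None
    order: str = ORDER_NA

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.target not in OBJECTS:
            raise ValueError(f"target must be in {OBJECTS}")
        if self.context is not None:
            if self.context not in OBJECTS:
                raise ValueError(f"context must be in {OBJECTS} or None")
            if self.context == self.target:
                raise ValueError("target and context must differ")

    @property
    def key(self) -> str:
        """Canonical short string id, used as the row key in data tables."""
        if self.experiment == EXP1:
            return f"T{self.target}D{self.context or 0}"
        if self.context is None:
            return f"S{self.target}"
        return f"O{self.target}{self.context}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key


def exp1_conditions() -> list[ConditionLabel]:
    """All 16 Experiment 1 conditions: 12 with a distractor, 4 without."""
    out = [
        ConditionLabel(EXP1, t, d)
        for t in OBJECTS
        for d in OBJECTS
        if d != t
    ]
    out += [ConditionLabel(EXP1, t, None) for t in OBJECTS]
    return out


def exp2_conditions() -> list[ConditionLabel]:
    """All 16 Experiment 2 conditions: 12 ordered pairs, 4 singles.

    The ordered pair (first=i, second=j) is labelled with ``target=i``,
    ``context=j`` and ``order=target-first``.
    """
    out = [
        ConditionLabel(EXP2, i, j, TARGET_FIRST)
        for i, j in permutations(OBJECTS, 2)
    ]
    out += [ConditionLabel(EXP2, t, None) for t in OBJECTS]
    return out


def conditions_for(experiment: str) -> list[ConditionLabel]:
    if experiment == EXP1:
        return exp1_conditions()
    if experiment == EXP2:
        return exp2_conditions()
    raise ValueError(f"unknown experiment {experiment!r}")


def condition_keys(experiment: str) -> list[str]:
    return [c.key for c in conditions_for(experiment)]


def exp2_pair_keys(a: int, b: int) -> list[str]:
    """Keys of both presentation orders of the unordered target pair {a, b}."""
    if a == b:
        raise ValueError("pair members must differ")
    return [f"O{a}{b}", f"O{b}{a}"]


def target_pairs() -> list[tuple[int, int]]:
    """The 6 unordered pairs of the 4 objects."""
    return list(combinations(OBJECTS, 2))


def remaining_objects(a: int, b: int) -> tuple[int, int]:
    """The two objects not in the pair {a, b}."""
    rest = tuple(o for o in OBJECTS if o not in (a, b))
    if len(rest) != 2:
        raise ValueError("expected a pair of distinct objects")
    return rest
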