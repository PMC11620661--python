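"""The core in-memory container: condition-labelled multivariate patterns.

A :class:`PatternDataset` holds one participant x ROI worth of pattern
estimates: for every condition, 4 splits x (typically) 7 estimates, each
estimate a vector over vertices. Downstream stages (decoding, RDMs,
geometry) consume this container; the synthetic generator and the FIR
GLM both produce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

N_SPLITS = 4


@dataclass
class PatternDataset:
    """Condition-labelled pattern estimates organized into splits.

    Attributes
    ----------
    patterns:
        Array of shape ``(n_obs, n_vertices)``; one row per estimate.
    conditions:
        Condition key per row (see :mod:`vwmgeom.conditions`).
    splits:
        Split id per row, in ``1..4``.
    estimates:
        Estimate id within (condition, split), in ``1..n_estimates``.
    experiment:
        ``"exp1"`` or ``"exp2"``.
    meta:
        Free-form provenance (seed, generator parameters, participant
        and ROI ids, ...).
    """

    patterns: np.ndarray
    conditions: np.ndarray
    splits: np.ndarray
    estimates: np.ndarray
    experiment: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.splits = np.asarray(self.splits, dtype=int)
        self.estimates = np.asarray(self.estimates, dtype=int)
        n = self.patterns.shape[0]
        if not (len(self.conditions) == len(self.splits) == len(self.estimates) == n):
            raise ValueError("label arrays must match the number of pattern rows")
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("patterns contain non-finite values")

    @property
    def n_vertices(self) -> int:
        return self.patterns.shape[1]

    @property
    def condition_keys(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(c)
        return list(seen)

    @property
    def split_ids(self) -> list[int]:
        return sorted(set(self.splits.tolist()))

    def mask(self, conditions: Optional[Iterable[str]] = None,
             splits: Optional[Iterable[int]] = None) -> np.ndarray:
        """Boolean row mask selecting conditions and/or splits."""
        m = np.ones(len(self.conditions), dtype=bool)
        if conditions is not None:
            cond = set(conditions)
            m &= np.array([c in cond for c in self.conditions])
        if splits is not None:
            spl = set(splits)
            m &= np.array([s in spl for s in self.splits])
        return m

    def select(self, conditions: Optional[Iterable[str]] = None,
               splits: Optional[Iterable[int]] = None) -> "PatternDataset":
        m = self.mask(conditions, splits)
        return PatternDataset(
            patterns=self.patterns[m],
            conditions=self.conditions[m],
            splits=self.splits[m],
            estimates=self.estimates[m],
            experiment=self.experiment,
            meta=dict(self.meta),
        )

    def counts(self) -> pd.DataFrame:
        """Estimate counts per (condition, split)."""
        df = pd.DataFrame({"condition": self.conditions, "split": self.splits})
        return df.value_counts(["condition", "split"]).unstack(fill_value=0)

    def validate_balanced(self, conditions: Sequence[str],
                          n_estimates: int = 7) -> None:
        """Check every listed condition has ``n_estimates`` rows per split."""
        missing = []
        for c in conditions:
            for s in range(1, N_SPLITS + 1):
                n = int(np.sum(self.mask([c], [s])))
                if n != n_estimates:
                    missing.append((c, s, n))
        if missing:
            raise ValueError(
                "unbalanced dataset; (condition, split, count) != "
                f"{n_estimates}: {missing[:8]}"
            )

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: one row per estimate, vertex columns ``v0..``."""
        cols = [f"v{i}" for i in range(self.n_vertices)]
        df = pd.DataFrame(self.patterns, columns=cols)
        df.insert(0, "estimate", self.estimates)
        df.insert(0, "split", self.splits)
        df.insert(0, "condition", self.conditions)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, experiment: str,
                   meta: Optional[Mapping] = None) -> "PatternDataset":
        vcols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
        return cls(
            patterns=df[vcols].to_numpy(dtype=float),
            conditions=df["condition"].to_numpy(dtype=object),
            splits=df["split"].to_numpy(dtype=int),
            estimates=df["estimate"].to_numpy(dtype=int),
            experiment=experiment,
            meta=dict(meta or {}),
        )

    def equals(self, other: "PatternDataset") -> bool:
        return (
            self.experiment == other.experiment
            and self.patterns.shape == other.patterns.shape
            and np.array_equal(self.patterns, other.patterns)
            and np.array_equal(self.conditions, other.conditions)
            and np.array_equal(self.splits, other.splits)
            and np.array_equal(self.estimates, other.estimates)
        )
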