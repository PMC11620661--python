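"""Split-rotation linear decoding of condition-labelled patterns.

The scheme follows the 4-split cross-validation used throughout the
study: a linear support-vector classifier is trained on all estimates
from 3 splits (21 per class for single-condition classes) and tested on
the held-out split (7 per class); the rotation repeats with each split
held out once and accuracies are averaged. Cross-condition tasks train
in one context and test in another — both directions are enumerated and
averaged at the analysis level. Every pattern is z-normalized across
vertices before entering the classifier, removing amplitude differences
between conditions, ROIs and processing stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.svm import SVC

from .conditions import exp2_pair_keys, remaining_objects, target_pairs
from .patterns import N_SPLITS, PatternDataset

WITHIN = "within"
CROSS = "cross"

ANALYSES = (
    "exp1-cross-distractor",
    "exp1-distractor-presence",
    "exp1-distractor-decoding",
    "exp2-target-cross",
    "exp2-order",
)


def znorm(pattern: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Z-normalize one pattern across its vertices (sample-SD convention)."""
    x = np.asarray(pattern, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("pattern must be a vector with at least 2 vertices")
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("degenerate pattern: zero variance across vertices")
    return (x - x.mean()) / sd


def znorm_rows(patterns: np.ndarray, ddof: int = 1) -> np.ndarray:
    x = np.asarray(patterns, dtype=float)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("degenerate pattern: zero variance across vertices")
    return (x - x.mean(axis=1, keepdims=True)) / sd


def probit_transform(accuracy: float, n_estimates: int = 28,
                     eps: Optional[float] = None) -> float:
    """Inverse-normal-CDF transform of a decoding accuracy.

    Accuracies are clipped to ``[eps, 1 - eps]`` (default continuity
    correction ``eps = 1 / (2 * n_estimates)``) so perfect or zero
    accuracy maps to a finite value.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if eps is None:
        eps = 1.0 / (2 * n_estimates)
    return float(norm.ppf(np.clip(accuracy, eps, 1.0 - eps)))


@dataclass(frozen=True)
class DecodingTask:
    """One two-class decoding problem (possibly cross-context).

    Class sets are tuples of condition keys; multi-condition classes
    pool their estimates (Experiment 2 combines the two presentation
    orders of a pair this way). For within tasks test sets equal train
    sets; cross tasks are emitted as directed pairs whose accuracies
    are averaged at the analysis level.
    """

    analysis: str
    mode: str  # within | cross
    train_a: tuple[str, ...]
    train_b: tuple[str, ...]
    test_a: tuple[str, ...]
    test_b: tuple[str, ...]
    tag: str = ""

    def __post_init__(self) -> None:
        if set(self.train_a) & set(self.train_b):
            raise ValueError("training class sets must be disjoint")
        if set(self.test_a) & set(self.test_b):
            raise ValueError("test class sets must be disjoint")
        if self.mode not in (WITHIN, CROSS):
            raise ValueError("mode must be 'within' or 'cross'")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(
            self.train_a + self.train_b + self.test_a + self.test_b))


@dataclass
class DecodingResult:
    analysis: str
    mode: str
    accuracy: float
    accuracy_probit: float
    n_train_per_class: int
    n_test_per_class: int
    per_rotation: np.ndarray = field(repr=False, default=None)
    tag: str = ""


def _class_rows(data: PatternDataset, conditions: Sequence[str],
                splits: Sequence[int]) -> np.ndarray:
    return znorm_rows(data.patterns[data.mask(conditions, splits)])


def run_decoding(data: PatternDataset, task: DecodingTask,
                 seed: int = 0, C: float = 1.0) -> DecodingResult:
    """Run one task over the 4 split rotations and average accuracy.

    The classifier is a linear-kernel SVM with fixed cost ``C`` (the
    solver is deterministic for fixed data; ``seed`` is accepted for
    interface uniformity). Training and test splits never overlap.
    """
    splits = data.split_ids
    if len(splits) != N_SPLITS:
        raise ValueError(f"expected {N_SPLITS} splits, found {splits}")
    for c in task.conditions:
        for s in splits:
            if not np.any(data.mask([c], [s])):
                raise ValueError(f"condition {c!r} missing from split {s}")
    accs = []
    n_train = n_test = 0
    for test_split in splits:
        train_splits = [s for s in splits if s != test_split]
        xa = _class_rows(data, task.train_a, train_splits)
        xb = _class_rows(data, task.train_b, train_splits)
        ta = _class_rows(data, task.test_a, [test_split])
        tb = _class_rows(data, task.test_b, [test_split])
        if len(xa) != len(xb) or len(ta) != len(tb):
            raise ValueError("class imbalance across splits")
        clf = SVC(kernel="linear", C=C)
        x = np.vstack([xa, xb])
        y = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])
        clf.fit(x, y)
        pred = clf.predict(np.vstack([ta, tb]))
        truth = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
        accs.append(float(np.mean(pred == truth)))
        n_train, n_test = len(xa), len(ta)
    acc = float(np.mean(accs))
    return DecodingResult(
        analysis=task.analysis,
        mode=task.mode,
        accuracy=acc,
        accuracy_probit=probit_transform(acc, n_estimates=N_SPLITS * n_test),
        n_train_per_class=n_train,
        n_test_per_class=n_test,
        per_rotation=np.asarray(accs),
        tag=task.tag,
    )


def _exp1_key(t: int, d: Optional[int]) -> str:
    return f"T{t}D{d or 0}"


def enumerate_tasks(experiment: str, analysis: str) -> list[DecodingTask]:
    """All decoding tasks of one named analysis.

    * ``exp1-cross-distractor`` — per target pair {A, B} with the two
      remaining objects {C, D} as distractors: 2 within tasks (same
      distractor) and 2 directed cross tasks (train under C, test
      under D, and the reverse).
    * ``exp1-distractor-presence`` — per target pair: the no-distractor
      within task, the 2 distractor within tasks, and the 4 directed
      cross tasks between each distractor condition and no-distractor.
    * ``exp1-distractor-decoding`` — distractor identity with the
      target held constant.
    * ``exp2-target-cross`` — per target pair {A, B}: within/cross with
      partner C vs partner D, presentation orders pooled.
    * ``exp2-order`` — the two presentation orders of each pair.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}")
    if analysis.split("-")[0] != experiment:
        raise ValueError(f"analysis {analysis!r} is not defined for {experiment}")
    tasks: list[DecodingTask] = []

    if analysis == "exp1-cross-distractor":
        for a, b in target_pairs():
            c, d = remaining_objects(a, b)
            for dist in (c, d):
                pa, pb = (_exp1_key(a, dist),), (_exp1_key(b, dist),)
                tasks.append(DecodingTask(analysis, WITHIN, pa, pb, pa, pb,
                                          tag=f"T{a}{b}|D{dist}"))
            for tr, te in ((c, d), (d, c)):
                tasks.append(DecodingTask(
                    analysis, CROSS,
                    (_exp1_key(a, tr),), (_exp1_key(b, tr),),
                    (_exp1_key(a, te),), (_exp1_key(b, te),),
                    tag=f"T{a}{b}|D{tr}->D{te}"))
    elif analysis == "exp1-distractor-presence":
        for a, b in target_pairs():
            c, d = remaining_objects(a, b)
            none_a, none_b = (_exp1_key(a, None),), (_exp1_key(b, None),)
            tasks.append(DecodingTask(analysis, WITHIN, none_a, none_b,
                                      none_a, none_b, tag=f"T{a}{b}|none"))
            for dist in (c, d):
                pa, pb = (_exp1_key(a, dist),), (_exp1_key(b, dist),)
                tasks.append(DecodingTask(analysis, WITHIN, pa, pb, pa, pb,
                                          tag=f"T{a}{b}|D{dist}"))
                tasks.append(DecodingTask(analysis, CROSS, pa, pb,
                                          none_a, none_b,
                                          tag=f"T{a}{b}|D{dist}->none"))
                tasks.append(DecodingTask(analysis, CROSS, none_a, none_b,
                                          pa, pb, tag=f"T{a}{b}|none->D{dist}"))
    elif analysis == "exp1-distractor-decoding":
        for t in (1, 2, 3, 4):
            dists = [o for o in (1, 2, 3, 4) if o != t]
            for i in range(len(dists)):
                for j in range(i + 1, len(dists)):
                    pa = (_exp1_key(t, dists[i]),)
                    pb = (_exp1_key(t, dists[j]),)
                    tasks.append(DecodingTask(
                        analysis, WITHIN, pa, pb, pa, pb,
                        tag=f"D{dists[i]}{dists[j]}|T{t}"))
    elif analysis == "exp2-target-cross":
        for a, b in target_pairs():
            c, d = remaining_objects(a, b)
            cls = {p: tuple(exp2_pair_keys(*p))
                   for p in [(a, c), (b, c), (a, d), (b, d)]}
            for partner in (c, d):
                pa, pb = cls[(a, partner)], cls[(b, partner)]
                tasks.append(DecodingTask(analysis, WITHIN, pa, pb, pa, pb,
                                          tag=f"T{a}{b}|P{partner}"))
            for tr, te in ((c, d), (d, c)):
                tasks.append(DecodingTask(
                    analysis, CROSS, cls[(a, tr)], cls[(b, tr)],
                    cls[(a, te)], cls[(b, te)], tag=f"T{a}{b}|P{tr}->P{te}"))
    elif analysis == "exp2-order":
        for a, b in target_pairs():
            pa, pb = (f"O{a}{b}",), (f"O{b}{a}",)
            tasks.append(DecodingTask(analysis, WITHIN, pa, pb, pa, pb,
                                      tag=f"order{a}{b}"))
    return tasks


def run_analysis(data: PatternDataset, analysis: str,
                 seed: int = 0, C: float = 1.0) -> pd.DataFrame:
    """Run all tasks of an analysis; one tidy row per task."""
    tasks = enumerate_tasks(data.experiment, analysis)
    rows = []
    for task in tasks:
        r = run_decoding(data, task, seed=seed, C=C)
        rows.append((analysis, task.tag, r.mode, r.accuracy, r.accuracy_probit,
                     r.n_train_per_class, r.n_test_per_class))
    return pd.DataFrame(rows, columns=[
        "analysis", "task", "mode", "accuracy", "accuracy_probit",
        "n_train_per_class", "n_test_per_class"])


def summarize_analysis(table: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per mode (cross directions average together here)."""
    return (table.groupby("mode", as_index=False)
            .agg(accuracy=("accuracy", "mean"),
                 accuracy_probit=("accuracy_probit", "mean"),
                 n_tasks=("accuracy", "size")))


def decode_timecourse(per_tr_data: Sequence[PatternDataset],
                      task: DecodingTask, seed: int = 0,
                      C: float = 1.0) -> np.ndarray:
    """Accuracy at each FIR lag (see :func:`fir.decode_per_tr_patterns`)."""
    return np.array([
        run_decoding(d, task, seed=seed, C=C).accuracy for d in per_tr_data
    ])


def permute_labels_within_splits(data: PatternDataset, conditions: Sequence[str],
                                 seed: int) -> PatternDataset:
    """Null-hypothesis control: shuffle the given condition labels
    among their rows, separately within each split."""
    rng = np.random.default_rng(seed)
    out = data.select()
    cond = set(conditions)
    for s in out.split_ids:
        idx = np.flatnonzero(out.mask(cond, [s]))
        out.conditions[idx] = out.conditions[rng.permutation(idx)]
    return out
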