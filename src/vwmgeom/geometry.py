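"""Representational geometry: RDMs, classical MDS, and line angles.

For each cross-decoding quartet {T1C1, T2C1, T1C2, T2C2} (two targets
under two contexts) a 4x4 representational dissimilarity matrix is
filled with the 6 pairwise decoding accuracies, embedded in 3D by
classical (Torgerson) MDS — 4 points are fully captured by 3
dimensions — and summarized by two line angles:

* target-target angle — between the line T1C1->T2C1 and the line
  T1C2->T2C2 (target coding across contexts);
* context-context (distractor-distractor) angle — between T1C1->T1C2
  and T2C1->T2C2.

Angles are folded to [0, 90] degrees (lines, not vectors). Because a
3D angle is never negative, per-participant angles are biased upward
by noise; leave-one-participant-out group-averaged RDMs reduce that
bias, so group geometry is estimated by the jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .conditions import exp2_pair_keys, remaining_objects, target_pairs
from .decoding import WITHIN, DecodingTask, run_decoding
from .patterns import PatternDataset


@dataclass(frozen=True)
class Quartet:
    """4 condition sets laid out as (T1C1, T2C1, T1C2, T2C2)."""

    name: str
    labels: tuple[str, str, str, str]
    condition_sets: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.condition_sets) != 4:
            raise ValueError("a quartet needs exactly 4 condition sets")


@dataclass
class Rdm4:
    """Symmetric 4x4 dissimilarity matrix from pairwise decoding.

    ``entry`` records the convention: ``"above-chance"`` (accuracy -
    .5, the default — the chance baseline is not a distance and, left
    in, bends the MDS embedding) or ``"accuracy"`` (raw accuracy).
    """

    quartet: Quartet
    values: np.ndarray
    entry: str = "above-chance"

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.shape != (4, 4):
            raise ValueError("RDM must be 4x4")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("RDM must be symmetric with a zero diagonal")
        self.values = d


@dataclass
class Embedding3:
    """Classical-MDS coordinates and the Gram-matrix eigenvalues."""

    coords: np.ndarray  # (n_points, k), centered, by descending eigenvalue
    eigenvalues: np.ndarray
    truncated_mass: float  # |sum of negative eigenvalues| (non-Euclidean part)


def enumerate_quartets(experiment: str, analysis: str) -> list[Quartet]:
    """Quartets matching each cross-decoding analysis."""
    quartets = []
    if analysis == "exp1-cross-distractor":
        for a, b in target_pairs():
            c, d = remaining_objects(a, b)
            quartets.append(Quartet(
                name=f"T{a}{b}|D{c}{d}",
                labels=(f"T{a}D{c}", f"T{b}D{c}", f"T{a}D{d}", f"T{b}D{d}"),
                condition_sets=((f"T{a}D{c}",), (f"T{b}D{c}",),
                                (f"T{a}D{d}",), (f"T{b}D{d}",)),
            ))
    elif analysis == "exp1-distractor-presence":
        for a, b in target_pairs():
            for dist in remaining_objects(a, b):
                quartets.append(Quartet(
                    name=f"T{a}{b}|D{dist}0",
                    labels=(f"T{a}D{dist}", f"T{b}D{dist}",
                            f"T{a}D0", f"T{b}D0"),
                    condition_sets=((f"T{a}D{dist}",), (f"T{b}D{dist}",),
                                    (f"T{a}D0",), (f"T{b}D0",)),
                ))
    elif analysis == "exp2-target-cross":
        for a, b in target_pairs():
            c, d = remaining_objects(a, b)
            quartets.append(Quartet(
                name=f"T{a}{b}|P{c}{d}",
                labels=(f"{a}+{c}", f"{b}+{c}", f"{a}+{d}", f"{b}+{d}"),
                condition_sets=(tuple(exp2_pair_keys(a, c)),
                                tuple(exp2_pair_keys(b, c)),
                                tuple(exp2_pair_keys(a, d)),
                                tuple(exp2_pair_keys(b, d))),
            ))
    else:
        raise ValueError(f"no quartets defined for analysis {analysis!r}")
    return quartets


def build_rdm4(data: PatternDataset, quartet: Quartet,
               seed: int = 0, C: float = 1.0,
               entry: str = "above-chance") -> Rdm4:
    """Pairwise within-mode decoding among the quartet's 4 conditions.

    With the default ``entry="above-chance"`` each cell holds accuracy
    minus .5 (chance); individual cells may dip slightly below zero by
    sampling noise and are left untouched so that group averaging stays
    unbiased (the embedding step floors dissimilarities at zero).
    ``entry="probit"`` stores the probit-transformed accuracy instead,
    which undoes the sigmoidal compression of accuracy at high signal
    and therefore recovers intermediate planted angles with less bias;
    ``entry="accuracy"`` keeps the raw accuracy including its chance
    baseline.
    """
    if entry not in ("above-chance", "accuracy", "probit"):
        raise ValueError("entry must be 'above-chance', 'accuracy' or 'probit'")
    d = np.zeros((4, 4))
    for i, j in combinations(range(4), 2):
        task = DecodingTask(
            analysis="rdm", mode=WITHIN,
            train_a=quartet.condition_sets[i],
            train_b=quartet.condition_sets[j],
            test_a=quartet.condition_sets[i],
            test_b=quartet.condition_sets[j],
            tag=f"{quartet.name}:{i}{j}",
        )
        res = run_decoding(data, task, seed=seed, C=C)
        if entry == "above-chance":
            acc = res.accuracy - 0.5
        elif entry == "probit":
            acc = res.accuracy_probit
        else:
            acc = res.accuracy
        d[i, j] = d[j, i] = acc
    return Rdm4(quartet=quartet, values=d, entry=entry)


def classical_mds(rdm: np.ndarray | Rdm4, k: int = 3) -> Embedding3:
    """Torgerson scaling of a dissimilarity matrix.

    Squared dissimilarities are double-centered, eigendecomposed, and
    the top-``k`` non-negative eigenpairs give the coordinates.
    Negative eigenvalues (non-Euclidean noise) are truncated to zero
    and their magnitude reported.
    """
    d = rdm.values if isinstance(rdm, Rdm4) else np.asarray(rdm, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = d.shape[0]
    d = np.clip(d, 0.0, None)  # sampling noise can push dissimilarities < 0
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    truncated = float(-np.sum(evals[evals < 0]))
    lam = np.clip(evals[:k], 0.0, None)
    coords = evecs[:, :k] * np.sqrt(lam)
    # deterministic axis orientation
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return Embedding3(coords=coords, eigenvalues=evals,
                      truncated_mass=truncated)


def angle_between_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two direction vectors, folded to [0, 90] degrees.

    Computed from the orthogonal rejection via ``arctan2`` rather than
    ``arccos`` of the normalized dot product, which loses precision for
    nearly parallel or nearly orthogonal vectors; identical vectors
    yield exactly 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("degenerate geometry: zero-length line")
    dot = float(a @ b)
    rej = a - (dot / (nb * nb)) * b
    ang = np.degrees(np.arctan2(np.linalg.norm(rej) * nb, abs(dot)))
    return float(min(ang, 90.0))


def line_angle(p1: np.ndarray, p2: np.ndarray,
               q1: np.ndarray, q2: np.ndarray) -> float:
    """Angle in degrees, folded to [0, 90], between lines p1p2 and q1q2."""
    a = np.asarray(p2, float) - np.asarray(p1, float)
    b = np.asarray(q2, float) - np.asarray(q1, float)
    return angle_between_deg(a, b)


def rdm_angles(rdm: Rdm4 | np.ndarray) -> dict[str, float]:
    """Target-target and context-context line angles of one RDM."""
    x = classical_mds(rdm).coords
    return {
        "target_target": line_angle(x[0], x[1], x[2], x[3]),
        "context_context": line_angle(x[0], x[2], x[1], x[3]),
    }


def participant_rdms(datasets: Sequence[PatternDataset],
                     quartets: Sequence[Quartet],
                     seed: int = 0, C: float = 1.0,
                     entry: str = "above-chance") -> np.ndarray:
    """RDMs for every participant x quartet; shape (N, Q, 4, 4)."""
    out = np.zeros((len(datasets), len(quartets), 4, 4))
    for p, data in enumerate(datasets):
        for q, quartet in enumerate(quartets):
            out[p, q] = build_rdm4(data, quartet, seed=seed, C=C,
                                   entry=entry).values
    return out


def participant_angles(rdms: np.ndarray,
                       quartets: Sequence[Quartet]) -> pd.DataFrame:
    """Per-participant angles, averaged over quartets.

    ``rdms`` is the (N, Q, 4, 4) array from :func:`participant_rdms`.
    """
    rows = []
    for p in range(rdms.shape[0]):
        per_q = [rdm_angles(rdms[p, q]) for q in range(rdms.shape[1])]
        rows.append((
            p,
            float(np.mean([a["target_target"] for a in per_q])),
            float(np.mean([a["context_context"] for a in per_q])),
        ))
    return pd.DataFrame(rows, columns=["participant", "target_target",
                                       "context_context"])


def jackknife_group_angles(rdms: np.ndarray,
                           quartets: Sequence[Quartet]) -> pd.DataFrame:
    """Leave-one-participant-out group-RDM angles.

    For each left-out participant the remaining N-1 RDMs are averaged
    entrywise per quartet, embedded, and their angles averaged over
    quartets — yielding N estimates per angle kind. Group averaging
    before embedding cancels independent noise and so reduces the
    positive angle bias of per-participant estimates.
    """
    n = rdms.shape[0]
    if n < 3:
        raise ValueError("jackknife needs at least 3 participants")
    rows = []
    for left_out in range(n):
        keep = [p for p in range(n) if p != left_out]
        group = rdms[keep].mean(axis=0)  # (Q, 4, 4)
        per_q = [rdm_angles(group[q]) for q in range(group.shape[0])]
        rows.append((
            left_out,
            float(np.mean([a["target_target"] for a in per_q])),
            float(np.mean([a["context_context"] for a in per_q])),
        ))
    return pd.DataFrame(rows, columns=["left_out", "target_target",
                                       "context_context"])


def summarize_angles(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SE of each angle column of a participant/jackknife table."""
    out = []
    for col in ("target_target", "context_context"):
        v = table[col].to_numpy()
        out.append((col, float(v.mean()),
                    float(v.std(ddof=1) / np.sqrt(len(v)))))
    return pd.DataFrame(out, columns=["kind", "mean_deg", "se_deg"])
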