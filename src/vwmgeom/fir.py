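"""Finite-impulse-response GLM estimation of condition responses.

Because every condition occurs only once per run and inter-trial gaps
are short relative to the hemodynamic lag, single-run estimates are
unreliable; instead runs within a split are combined: each split of 7
runs yields the 7 leave-one-run-out 6-run GLMs, and each split of 6
runs yields the six 5-run GLMs plus the full 6-run GLM — always 7 beta
estimates per split, hence 28 pattern estimates per condition over the
4 splits.

The FIR model estimates one amplitude per TR from trial onset up to
24 s (30 TRs of 0.8 s) per condition, with no assumed response shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import RunDesign, TR_S
from .patterns import PatternDataset

N_LAGS = 30  # TRs modelled from trial onset (24 s at TR = 0.8 s)


@dataclass(frozen=True)
class WindowSpec:
    """A trial-relative averaging window, half-open ``[start_s, end_s)``."""

    name: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_s < self.end_s <= N_LAGS * TR_S):
            raise ValueError("window must satisfy 0 <= start < end <= 24 s")

    def tr_indices(self, tr_s: float = TR_S) -> np.ndarray:
        """FIR lags whose start times fall inside the window."""
        lags = np.arange(N_LAGS)
        starts = lags * tr_s
        idx = lags[(starts >= self.start_s - 1e-9) & (starts < self.end_s - 1e-9)]
        if idx.size == 0:
            raise ValueError(f"window {self.name!r} covers no TR start")
        return idx


#: delay period of Experiment 1 (probe onset at 12.5 s)
EXP1_DELAY = WindowSpec("exp1-delay", 9.6, 12.0)
#: delay period of Experiment 2 (probe onset at 13 s)
EXP2_DELAY = WindowSpec("exp2-delay", 10.4, 12.8)
#: encoding period of Experiment 2
EXP2_ENCODING = WindowSpec("exp2-encoding", 4.8, 8.0)


@dataclass
class FirDesign:
    """Per-run FIR regressor blocks plus the shared column index."""

    runs: list[RunDesign]
    blocks: list[np.ndarray]          # per run: (n_tr, 30 * n_conditions)
    conditions: list[str]             # column-block order
    #: (condition, lag) per FIR column
    columns: list[tuple[str, int]]

    @property
    def n_fir_columns(self) -> int:
        return len(self.columns)


def build_fir_design(runs: Sequence[RunDesign]) -> FirDesign:
    """Build FIR indicator regressors for a list of runs.

    Each condition gets 30 columns; column (c, k) is 1 at TR ``t + k``
    for every trial of condition c starting at TR ``t``. Trials running
    past the end of a run have the out-of-run lags clipped (with a
    warning). Per-run intercepts are added at estimation time.
    """
    if not runs:
        raise ValueError("no runs given")
    conditions = sorted({c for r in runs for c in r.conditions})
    col_of = {c: i for i, c in enumerate(conditions)}
    blocks = []
    clipped = 0
    for run in runs:
        x = np.zeros((run.n_tr, N_LAGS * len(conditions)))
        for onset_tr, cond in zip(run.onset_tr, run.conditions):
            stop = min(onset_tr + N_LAGS, run.n_tr)
            if stop < onset_tr + N_LAGS:
                clipped += 1
            lags = np.arange(stop - onset_tr)
            x[onset_tr + lags, col_of[cond] * N_LAGS + lags] += 1.0
        blocks.append(x)
    if clipped:
        warnings.warn(f"{clipped} trial(s) extend past the run end; "
                      "their trailing FIR lags were clipped")
    columns = [(c, k) for c in conditions for k in range(N_LAGS)]
    return FirDesign(runs=list(runs), blocks=blocks,
                     conditions=conditions, columns=columns)


def enumerate_run_combinations(run_ids: Sequence[int],
                               allow_any_size: bool = False) -> list[tuple[int, ...]]:
    """Run subsets used for one split's GLMs.

    7 runs -> the 7 leave-one-out 6-run subsets; 6 runs -> the 6
    leave-one-out 5-run subsets plus the full 6-run set. Either way, 7
    combinations. Other sizes raise unless ``allow_any_size`` is set,
    in which case all leave-one-out subsets plus the full set are used.
    """
    ids = tuple(run_ids)
    n = len(ids)
    loo = [tuple(x for x in ids if x != drop) for drop in ids]
    if n == 7:
        return loo
    if n == 6 or (allow_any_size and n >= 2):
        return loo + [ids]
    raise ValueError(
        f"unsupported split size {n}; expected 6 or 7 runs per split "
        "(pass allow_any_size=True to override)"
    )


@dataclass
class BetaEstimate:
    """FIR amplitude estimates from one run combination.

    ``beta`` has shape ``(30, n_conditions, n_vertices)``.
    """

    beta: np.ndarray
    conditions: list[str]
    split: int
    combination_id: int
    run_ids: tuple[int, ...]

    def pattern(self, condition: str, lags: np.ndarray) -> np.ndarray:
        ci = self.conditions.index(condition)
        return self.beta[lags, ci, :].mean(axis=0)


def estimate_betas(timeseries: Sequence[np.ndarray], fir: FirDesign,
                   subsets: Optional[dict[int, list[tuple[int, ...]]]] = None,
                   ) -> list[BetaEstimate]:
    """Ordinary-least-squares FIR amplitudes for every run combination.

    Parameters
    ----------
    timeseries:
        One ``(n_tr, n_vertices)`` array per run, ordered as
        ``fir.runs``.
    fir:
        Design from :func:`build_fir_design`.
    subsets:
        Optional mapping split id -> run-id subsets; by default the
        standard combinations from :func:`enumerate_run_combinations`.

    Returns one :class:`BetaEstimate` per (split, combination).
    """
    if len(timeseries) != len(fir.runs):
        raise ValueError("one time series per run required")
    run_index = {r.run_id: i for i, r in enumerate(fir.runs)}
    split_runs: dict[int, list[int]] = {}
    for r in fir.runs:
        split_runs.setdefault(r.split, []).append(r.run_id)
    if subsets is None:
        subsets = {s: enumerate_run_combinations(ids)
                   for s, ids in split_runs.items()}

    n_cond = len(fir.conditions)
    out = []
    for split in sorted(subsets):
        for comb_id, subset in enumerate(subsets[split], start=1):
            xs, ys = [], []
            for j, rid in enumerate(subset):
                i = run_index[rid]
                block = fir.blocks[i]
                icept = np.zeros((block.shape[0], len(subset)))
                icept[:, j] = 1.0
                xs.append(np.hstack([block, icept]))
                ys.append(np.asarray(timeseries[i], dtype=float))
            x = np.vstack(xs)
            y = np.vstack(ys)
            used = x.any(axis=0)  # FIR columns absent from these runs stay 0
            beta_full = np.zeros((x.shape[1], y.shape[1]))
            sol, _, rank, _ = np.linalg.lstsq(x[:, used], y, rcond=None)
            if rank < int(used.sum()):
                bad = int(used.sum()) - rank
                raise np.linalg.LinAlgError(
                    f"rank-deficient FIR design for split {split} subset "
                    f"{subset}: {bad} collinear column(s)"
                )
            beta_full[used] = sol
            beta = beta_full[: N_LAGS * n_cond].reshape(n_cond, N_LAGS, -1)
            out.append(BetaEstimate(
                beta=np.transpose(beta, (1, 0, 2)),
                conditions=list(fir.conditions),
                split=split,
                combination_id=comb_id,
                run_ids=tuple(subset),
            ))
    return out


def average_window(betas: Sequence[BetaEstimate], window: WindowSpec,
                   experiment: str = "exp1") -> PatternDataset:
    """Average FIR betas over a trial window into condition patterns.

    Yields one pattern per (condition, split, combination); with the
    standard combination scheme that is 4 splits x 7 estimates = 28
    patterns per condition.
    """
    lags = window.tr_indices()
    rows, conds, splits, ests = [], [], [], []
    for b in betas:
        for c in b.conditions:
            rows.append(b.pattern(c, lags))
            conds.append(c)
            splits.append(b.split)
            ests.append(b.combination_id)
    return PatternDataset(
        patterns=np.asarray(rows),
        conditions=np.asarray(conds, dtype=object),
        splits=np.asarray(splits),
        estimates=np.asarray(ests),
        experiment=experiment,
        meta={"window": window.name, "lags": lags.tolist()},
    )


def decode_per_tr_patterns(betas: Sequence[BetaEstimate],
                           experiment: str = "exp1") -> list[PatternDataset]:
    """One PatternDataset per FIR lag (for time-resolved decoding)."""
    out = []
    for k in range(N_LAGS):
        w = np.array([k])
        rows, conds, splits, ests = [], [], [], []
        for b in betas:
            for c in b.conditions:
                rows.append(b.pattern(c, w))
                conds.append(c)
                splits.append(b.split)
                ests.append(b.combination_id)
        out.append(PatternDataset(
            patterns=np.asarray(rows),
            conditions=np.asarray(conds, dtype=object),
            splits=np.asarray(splits),
            estimates=np.asarray(ests),
            experiment=experiment,
            meta={"lag": k},
        ))
    return out


def condition_timecourses(betas: Sequence[BetaEstimate]) -> pd.DataFrame:
    """Tidy per-condition beta time courses (mean and SE over vertices,
    averaged over all estimates), mirroring the ROI response plots."""
    if not betas:
        raise ValueError("no beta estimates")
    conds = betas[0].conditions
    stack = np.stack([b.beta for b in betas])  # (est, lag, cond, vertex)
    mean_over_est = stack.mean(axis=0)
    rows = []
    for ci, c in enumerate(conds):
        for k in range(N_LAGS):
            v = mean_over_est[k, ci]
            rows.append((c, k, k * TR_S, float(v.mean()),
                         float(v.std(ddof=1) / np.sqrt(v.size))))
    return pd.DataFrame(rows, columns=["condition", "tr", "time_s",
                                       "mean_beta", "se"])
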