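"""Run designs: trial orders, onsets and split structure.

Each run presents all 16 conditions of an experiment exactly once, in a
random order, with randomized inter-trial blank periods. Runs are
organized into 4 independent splits (2 scan sessions x odd/even runs in
the real experiments); the decoding stage rotates over these splits.

Timing follows the experimental protocols: TR = 0.8 s; Experiment 1
trials are 15 s long with an 8-s blank at the start and end of the run
and 15 inter-trial blanks of which three are 8 s and twelve are 2 s,
randomly placed (run length 5 min 4 s). Experiment 2 trials are 15.2 s
long; its inter-trial blanks are three 8-s and twelve 2.4-s periods,
chosen so that the run lasts the protocol's 5 min 12 s and every trial
onset coincides with a TR onset. Experiment 1 onsets are jittered
relative to the TR grid by the blank placement and are rounded to the
nearest TR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditions import EXP1, EXP2, EXPERIMENTS, condition_keys

TR_S = 0.8
N_SPLITS = 4

_TIMING = {
    # trial_s, edge_blank_s, long blanks (count, s), short blanks (count, s)
    EXP1: dict(trial_s=15.0, edge_s=8.0, n_long=3, long_s=8.0, n_short=12, short_s=2.0),
    EXP2: dict(trial_s=15.2, edge_s=8.0, n_long=3, long_s=8.0, n_short=12, short_s=2.4),
}


@dataclass
class RunDesign:
    """Trial schedule of one run: condition keys and onset times."""

    experiment: str
    run_id: int
    split: int  # 1..4
    onsets_s: np.ndarray  # trial onsets, seconds, on the TR grid
    conditions: list[str]  # condition key per trial
    run_length_s: float
    trial_length_s: float
    tr_s: float = TR_S

    @property
    def n_trials(self) -> int:
        return len(self.conditions)

    @property
    def n_tr(self) -> int:
        return int(round(self.run_length_s / self.tr_s))

    @property
    def onset_tr(self) -> np.ndarray:
        """Trial onsets as TR indices (onsets are already on the grid)."""
        return np.rint(self.onsets_s / self.tr_s).astype(int)


def _single_run(experiment: str, run_id: int, split: int,
                rng: np.random.Generator) -> RunDesign:
    t = _TIMING[experiment]
    keys = condition_keys(experiment)
    order = rng.permutation(len(keys))
    conditions = [keys[i] for i in order]

    n_gaps = len(keys) - 1
    gaps = np.full(n_gaps, t["short_s"])
    long_pos = rng.choice(n_gaps, size=t["n_long"], replace=False)
    gaps[long_pos] = t["long_s"]

    onsets = np.empty(len(keys))
    onsets[0] = t["edge_s"]
    for i in range(1, len(keys)):
        onsets[i] = onsets[i - 1] + t["trial_s"] + gaps[i - 1]
    run_length = onsets[-1] + t["trial_s"] + t["edge_s"]
    # protocol sanity: run length is fixed by the blank budget
    onsets = np.rint(onsets / TR_S) * TR_S  # round onsets to the TR grid
    return RunDesign(
        experiment=experiment,
        run_id=run_id,
        split=split,
        onsets_s=onsets,
        conditions=conditions,
        run_length_s=float(run_length),
        trial_length_s=t["trial_s"],
    )


def build_design(experiment: str, n_runs_per_split: int = 7,
                 seed: int | None = None) -> list[RunDesign]:
    """Build the full multi-run design: 4 splits x ``n_runs_per_split`` runs.

    Parameters
    ----------
    experiment:
        ``"exp1"`` or ``"exp2"``.
    n_runs_per_split:
        Runs per split (at least 2; the protocols used 6 or 7).
    seed:
        Seed for trial orders and blank placement (mandatory for
        reproducibility).

    Returns
    -------
    list of :class:`RunDesign`, ordered by split then run.
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    if n_runs_per_split < 2:
        raise ValueError("need at least 2 runs per split")
    if seed is None:
        raise ValueError("a seed is required for a reproducible design")
    rng = np.random.default_rng(seed)
    runs = []
    run_id = 0
    for split in range(1, N_SPLITS + 1):
        for _ in range(n_runs_per_split):
            runs.append(_single_run(experiment, run_id, split, rng))
            run_id += 1
    return runs
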