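"""Decoding accuracy as a function of underlying signal strength.

Comparing decoding accuracies across conditions assumes accuracy tracks
signal strength linearly. These simulations show that the relation is
sigmoidal — flat at the floor and ceiling — and that a probit transform
(inverse normal CDF) of accuracy restores a mostly linear relation
except exactly at chance.

Signal strength ``s`` is defined as the Mahalanobis distance between
the two class means under unit isotropic Gaussian noise, which gives
the ideal-observer accuracy the closed form ``Phi(s / 2)``; its probit
is exactly ``s / 2``, linear in ``s``. The empirical decoder is the
same linear SVM used by the pattern-decoding stage, trained on finite
samples, so its accuracy lies below the ideal curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.svm import SVC

from .decoding import probit_transform

DEFAULT_GRID = tuple(np.round(np.arange(0.0, 8.01, 0.5), 2))


@dataclass(frozen=True)
class SimCase:
    """One simulated decoding scenario.

    ``noise_sd_b`` lets the second class have a different noise scale
    (unequal-variance cases); signal strength is always expressed in
    units of the first class's unit noise.
    """

    name: str
    n_vertices: int = 50
    n_train: int = 20
    n_test: int = 100
    noise_sd_b: float = 1.0
    signal_grid: tuple[float, ...] = DEFAULT_GRID
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(self.signal_grid)
        if len(grid) < 3:
            raise ValueError("signal grid needs at least 3 points")
        if grid[0] != 0.0 or any(b < a for a, b in zip(grid, grid[1:])):
            raise ValueError("signal grid must be ascending and start at 0")
        if self.n_train < 2:
            raise ValueError("need at least 2 training patterns per class")


@dataclass
class SimCurve:
    case: SimCase
    s: np.ndarray
    accuracy: np.ndarray
    accuracy_probit: np.ndarray
    ideal: np.ndarray            # Phi(s / 2)
    ideal_probit: np.ndarray     # s / 2


#: the default battery: vertex count x training-set size, plus
#: unequal-variance variants
def default_cases(n_reps: int = 100, seed: int = 0) -> list[SimCase]:
    cases = []
    i = 0
    for nv in (20, 200):
        for nt in (10, 20, 40):
            cases.append(SimCase(name=f"v{nv}-n{nt}", n_vertices=nv,
                                 n_train=nt, n_reps=n_reps, seed=seed + i))
            i += 1
    for nv in (20, 200):
        for sd_b in (1.5, 2.0):
            # larger class-B noise lowers effective discriminability, so
            # the grid stretches accordingly to still span floor-to-ceiling
            grid = tuple(np.round(np.arange(0.0, 16.01, 1.0) * sd_b / 2.0, 2))
            cases.append(SimCase(name=f"v{nv}-n20-sd{sd_b}", n_vertices=nv,
                                 n_train=20, noise_sd_b=sd_b,
                                 signal_grid=grid, n_reps=n_reps,
                                 seed=seed + i))
            i += 1
    return cases


def simulate_case(case: SimCase, C: float = 1.0) -> SimCurve:
    """Monte-Carlo accuracy curve over the case's signal grid.

    Per signal strength and repetition: draw training and test samples
    of two Gaussian classes whose means are ``s`` apart (Mahalanobis,
    unit noise for class A), train the linear SVM, record test
    accuracy; average over repetitions.
    """
    rng = np.random.default_rng(case.seed)
    s_grid = np.asarray(case.signal_grid, dtype=float)
    acc = np.zeros(len(s_grid))
    for si, s in enumerate(s_grid):
        hits = 0
        total = 0
        for _ in range(case.n_reps):
            delta = np.zeros(case.n_vertices)
            delta[0] = s  # separation along one axis; rotation-invariant
            xa = rng.normal(size=(case.n_train, case.n_vertices))
            xb = delta + case.noise_sd_b * rng.normal(
                size=(case.n_train, case.n_vertices))
            ta = rng.normal(size=(case.n_test, case.n_vertices))
            tb = delta + case.noise_sd_b * rng.normal(
                size=(case.n_test, case.n_vertices))
            clf = SVC(kernel="linear", C=C)
            clf.fit(np.vstack([xa, xb]),
                    np.r_[np.zeros(case.n_train), np.ones(case.n_train)])
            pred = clf.predict(np.vstack([ta, tb]))
            truth = np.r_[np.zeros(case.n_test), np.ones(case.n_test)]
            hits += int(np.sum(pred == truth))
            total += truth.size
        acc[si] = hits / total
    n_eff = case.n_reps * 2 * case.n_test
    probit = np.array([probit_transform(a, n_estimates=n_eff) for a in acc])
    return SimCurve(
        case=case, s=s_grid, accuracy=acc, accuracy_probit=probit,
        ideal=norm.cdf(s_grid / 2.0), ideal_probit=s_grid / 2.0,
    )


def _r2_linear(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of the least-squares line y ~ x; NaN if y is constant."""
    if np.allclose(y, y[0]):
        return float("nan")
    slope, icept = np.polyfit(x, y, 1)
    resid = y - (slope * x + icept)
    return float(1.0 - np.sum(resid ** 2) / np.sum((y - y.mean()) ** 2))


def linearity_report(curves: Sequence[SimCurve],
                     midrange: tuple[float, float] = (1.0, 4.0)) -> pd.DataFrame:
    """R^2 of accuracy (raw and probit) against signal strength.

    Computed over the full grid and over the mid-range band where the
    raw relation is closest to linear; flags cases where the probit
    transform improves full-range linearity (the expected outcome
    everywhere except degenerate constant curves).
    """
    if not curves:
        raise ValueError("need at least one curve")
    rows = []
    for cv in curves:
        mid = (cv.s >= midrange[0]) & (cv.s <= midrange[1])
        r2_raw_full = _r2_linear(cv.s, cv.accuracy)
        r2_pro_full = _r2_linear(cv.s, cv.accuracy_probit)
        rows.append({
            "case": cv.case.name,
            "r2_raw_mid": _r2_linear(cv.s[mid], cv.accuracy[mid]),
            "r2_probit_mid": _r2_linear(cv.s[mid], cv.accuracy_probit[mid]),
            "r2_raw_full": r2_raw_full,
            "r2_probit_full": r2_pro_full,
            "probit_improves": bool(r2_pro_full > r2_raw_full)
            if np.isfinite(r2_raw_full) and np.isfinite(r2_pro_full) else False,
            "degenerate": not np.isfinite(r2_raw_full),
        })
    return pd.DataFrame(rows)


def curve_table(curve: SimCurve) -> pd.DataFrame:
    """Tidy export of one simulated curve."""
    return pd.DataFrame({
        "case": curve.case.name,
        "s": curve.s,
        "accuracy": curve.accuracy,
        "accuracy_probit": curve.accuracy_probit,
        "ideal": curve.ideal,
        "ideal_probit": curve.ideal_probit,
    })
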