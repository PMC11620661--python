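"""Synthetic vertex patterns and run time series with planted geometry.

The generator plants a controllable representational geometry and then
draws noisy pattern estimates (and, optionally, run time series) from
it, so that every downstream stage — decoding, cross-decoding ratios,
RDM/MDS angles — can be validated against known ground truth.

Geometry model
--------------
The 4 memory objects are placed at the vertices of a regular
tetrahedron inside a 3-dimensional *target subspace*, so every object
pair is equally separable. Each *context* (Experiment 1: distractor
identity or absence; Experiment 2: partner-target identity) carries its
own copy of that subspace. The copies are built from an equicorrelated
basis

    f_mk = sqrt(cos theta) * g_m + sqrt(1 - cos theta) * e_mk

with ``g_m`` and all ``e_mk`` orthonormal, which makes the angle
between corresponding target-difference vectors in any two contexts
*exactly* ``theta``: for ``theta = 0`` target coding is identical in
every context (cross-decoding generalizes fully), for ``theta = 90``
the target codes of different contexts occupy mutually orthogonal
subspaces (no generalization).

Each distractor/partner context additionally contributes its own
orthogonal offset axis scaled by ``context_amplitude`` (so context
identity is itself decodable); Experiment 2 ordered pairs add an
order-tagging component scaled by ``order_amplitude``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .conditions import EXP1, EXPERIMENTS, conditions_for
from .design import RunDesign, TR_S, build_design
from .patterns import N_SPLITS, PatternDataset

#: estimates per (condition, split) produced by the run-combination GLM
N_ESTIMATES = 7

#: per-trial response profile over the 30 modelled TRs (model-free shape:
#: rise after ~1.5 s, sustained through the trial, return to baseline)
TRIAL_PROFILE = np.concatenate([
    np.zeros(2),
    np.linspace(0.0, 1.0, 6)[1:],       # TR 2..6 ramp
    np.ones(11),                        # TR 7..17 sustained
    np.linspace(1.0, 0.0, 8)[1:],       # TR 18..24 decay
    np.zeros(5),
])
assert TRIAL_PROFILE.shape == (30,)


@dataclass(frozen=True)
class GeometryParams:
    """Ground-truth parameters of the planted representational geometry.

    Parameters
    ----------
    n_vertices:
        Pattern dimensionality (default 200, the order of a mid-sized
        cortical ROI).
    theta_deg:
        Planted angle, in degrees within [0, 90], between the
        target-coding axes of any two contexts.
    target_amplitude:
        Half the Euclidean separation between two condition means that
        differ only in target identity (signal units; the default is
        calibrated so that the standard split-rotation decoder reaches
        roughly 75% within-context accuracy under the default noise).
    context_amplitude:
        Length of each context's offset component.
    order_amplitude:
        Length of the presentation-order component (Experiment 2 only).
    noise_sd:
        SD of the additive Gaussian vertex noise on each estimate.
    rho:
        Fraction of ``noise_sd`` shared by the 7 estimates of one
        split, emulating their shared-run estimation.
    seed:
        Seed for the random orthonormal basis and the noise draws.
    """

    n_vertices: int = 200
    theta_deg: float = 0.0
    target_amplitude: float = 1.9
    context_amplitude: float = 1.9
    order_amplitude: float = 0.95
    noise_sd: float = 1.0
    rho: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_deg <= 90.0:
            raise ValueError("theta_deg must lie in [0, 90]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.n_vertices < 3:
            raise ValueError("need at least 3 vertices")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth and provenance."""

    means: pd.DataFrame                 # condition x vertex ground truth
    data: PatternDataset                # noisy pattern estimates
    params: GeometryParams
    design: Optional[list[RunDesign]] = None
    timeseries: Optional[list[np.ndarray]] = None  # per run: (n_tr, n_vertices)


def _tetrahedron() -> np.ndarray:
    """Regular tetrahedron in 3D (rescaled to unit pair distance later)."""
    return np.array([
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ])

def _orthonormal(rng: np.random.Generator, n_vertices: int, k: int) -> np.ndarray:
    """k orthonormal direction vectors in R^n_vertices (rows)."""
    a = rng.normal(size=(n_vertices, k))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))  # deterministic sign convention
    return q.T


def _cos_theta(theta_deg: float) -> float:
    if theta_deg == 0.0:
        return 1.0
    if theta_deg == 90.0:
        return 0.0
    return float(np.cos(np.deg2rad(theta_deg)))


def _context_bases(rng: np.random.Generator, n_vertices: int,
                   n_contexts: int, theta_deg: float) -> list[np.ndarray]:
    """One 3 x n_vertices target-subspace basis per context.

    Built from the equicorrelated construction so corresponding basis
    vectors of any two contexts subtend exactly ``theta_deg``.
    """
    c = _cos_theta(theta_deg)
    dirs = _orthonormal(rng, n_vertices, 3 * (1 + n_contexts))
    g = dirs[:3]
    bases = []
    for k in range(n_contexts):
        e = dirs[3 * (1 + k): 3 * (2 + k)]
        bases.append(np.sqrt(c) * g + np.sqrt(1.0 - c) * e)
    return bases


def plant_geometry(params: GeometryParams, experiment: str) -> pd.DataFrame:
    """Construct the ground-truth condition means for one experiment.

    Returns a DataFrame indexed by condition key with one column per
    vertex. The angle between same-pair target-difference vectors of
    any two contexts equals ``params.theta_deg`` by construction.
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    labels = conditions_for(experiment)
    contexts = [None, 1, 2, 3, 4]  # absent/single + 4 object identities
    n_ctx = len(contexts)
    required = 3 * (1 + n_ctx) + 4 + 4  # target bases + context offsets + order tags
    if params.n_vertices < required:
        raise ValueError(
            f"n_vertices={params.n_vertices} too small; need >= {required} "
            "to hold the planted orthonormal directions"
        )
    rng = np.random.default_rng(params.seed)
    bases = _context_bases(rng, params.n_vertices, n_ctx, params.theta_deg)
    basis_of = dict(zip(contexts, bases))
    # object offsets for context identity; context None carries no offset
    w = _orthonormal(rng, params.n_vertices, 4)
    # order-tagging axes (used by exp2 ordered pairs only)
    z = _orthonormal(rng, params.n_vertices, 4)

    tet = _tetrahedron()
    tet = tet * (2.0 / np.linalg.norm(tet[0] - tet[1]))  # pairwise separation 2

    def target_code(t: int, context) -> np.ndarray:
        return params.target_amplitude * tet[t - 1] @ basis_of[context]

    rows = np.zeros((len(labels), params.n_vertices))
    for i, lab in enumerate(labels):
        if experiment == EXP1:
            rows[i] = target_code(lab.target, lab.context)
            if lab.context is not None:
                rows[i] += params.context_amplitude * w[lab.context - 1]
        else:
            if lab.context is None:  # single-target trial
                rows[i] = target_code(lab.target, None)
            else:  # ordered pair: first = target, second = context
                first, second = lab.target, lab.context
                rows[i] = target_code(first, second) + target_code(second, first)
                rows[i] += params.order_amplitude * (z[first - 1] - z[second - 1])
    return pd.DataFrame(rows, index=[lab.key for lab in labels])


def planted_target_angle(means: pd.DataFrame, pair: tuple[int, int] = (1, 2),
                         contexts: tuple = (3, 4)) -> float:
    """Measure the planted Experiment 1 target-coding angle from the means.

    Angle between the (T_a - T_b) difference vector under the first
    context and under the second (context ``None`` or 0 denotes the
    no-distractor condition). Equals ``theta_deg`` by construction.
    """
    from .geometry import angle_between_deg

    a, b = pair
    diffs = []
    for ctx in contexts:
        d = 0 if ctx in (None, 0) else ctx
        diffs.append((means.loc[f"T{a}D{d}"] - means.loc[f"T{b}D{d}"]).to_numpy())
    return angle_between_deg(diffs[0], diffs[1])


def sample_patterns(means: pd.DataFrame,
                    design: Optional[list[RunDesign]] = None,
                    *,
                    experiment: Optional[str] = None,
                    noise_sd: float = 1.0,
                    rho: float = 0.5,
                    n_estimates: int = N_ESTIMATES,
                    seed: Optional[int] = None,
                    params: Optional[GeometryParams] = None,
                    timeseries: bool = False,
                    ts_noise_sd: Optional[float] = None) -> SyntheticDataset:
    """Draw noisy pattern estimates (and optional run time series).

    Each (condition, split) receives ``n_estimates`` estimates::

        estimate = mean + shared_split_noise + unique_noise

    where the shared component (SD ``rho * noise_sd``) is common to the
    estimates of one split — emulating the shared runs of the
    leave-one-run-out GLM combinations — and the unique component (SD
    ``noise_sd``) is i.i.d. Estimates from different splits are fully
    independent. With ``timeseries=True`` each run's series is the sum
    of its trials' 30-TR profiles times their condition means, plus
    i.i.d. TR noise.
    """
    if seed is None:
        raise ValueError("a seed is required for a reproducible dataset")
    if design is None and experiment is None:
        raise ValueError("provide a design or an experiment id")
    if design is not None:
        experiment = design[0].experiment
        missing = {c for r in design for c in r.conditions} - set(means.index)
        if missing:
            raise ValueError(f"means missing conditions: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    mu = means.to_numpy(dtype=float)
    keys = list(means.index)
    n_vertices = mu.shape[1]

    rows, conds, splits, ests = [], [], [], []
    for ci, key in enumerate(keys):
        for s in range(1, N_SPLITS + 1):
            shared = rng.normal(0.0, rho * noise_sd, size=n_vertices) \
                if noise_sd > 0 else 0.0
            for e in range(1, n_estimates + 1):
                unique = rng.normal(0.0, noise_sd, size=n_vertices) \
                    if noise_sd > 0 else 0.0
                rows.append(mu[ci] + shared + unique)
                conds.append(key)
                splits.append(s)
                ests.append(e)

    data = PatternDataset(
        patterns=np.asarray(rows),
        conditions=np.asarray(conds, dtype=object),
        splits=np.asarray(splits),
        estimates=np.asarray(ests),
        experiment=experiment,
        meta={"seed": seed, "noise_sd": noise_sd, "rho": rho,
              "generator": "vwmgeom.synth.sample_patterns"},
    )

    series = None
    if timeseries:
        if design is None:
            raise ValueError("time series require a run design")
        sd_ts = noise_sd if ts_noise_sd is None else ts_noise_sd
        series = []
        key_index = {k: i for i, k in enumerate(keys)}
        for run in design:
            y = np.zeros((run.n_tr, n_vertices))
            for onset_tr, cond in zip(run.onset_tr, run.conditions):
                stop = min(onset_tr + 30, run.n_tr)
                y[onset_tr:stop] += (
                    TRIAL_PROFILE[: stop - onset_tr, None] * mu[key_index[cond]]
                )
            if sd_ts > 0:
                y += rng.normal(0.0, sd_ts, size=y.shape)
            series.append(y)

    return SyntheticDataset(means=means, data=data, params=params,
                            design=design, timeseries=series)


def generate_dataset(params: GeometryParams, experiment: str,
                     *, n_runs_per_split: int = 7,
                     timeseries: bool = False,
                     with_design: bool = False) -> SyntheticDataset:
    """Convenience wrapper: plant geometry, build a design, sample data.

    Sub-seeds for the geometry, the design and the noise are derived
    from ``params.seed`` so one integer reproduces the whole dataset.
    """
    ss = np.random.SeedSequence(params.seed).spawn(3)
    geom_seed, design_seed, noise_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss
    )
    means = plant_geometry(replace(params, seed=geom_seed), experiment)
    design = None
    if timeseries or with_design:
        design = build_design(experiment, n_runs_per_split, seed=design_seed)
    ds = sample_patterns(
        means, design, experiment=experiment, noise_sd=params.noise_sd,
        rho=params.rho, seed=noise_seed, params=params, timeseries=timeseries,
    )
    return ds
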