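"""End-to-end orchestration: simulate -> (GLM) -> decode -> geometry -> stats.

A :class:`PipelineConfig` fully determines a run: every stochastic
stage draws its sub-seed from the one master seed, so the same config
yields bit-identical result tables and a manifest with stable
checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conditions import EXP1, EXPERIMENTS
from .decoding import run_analysis
from .fir import (EXP1_DELAY, EXP2_DELAY, EXP2_ENCODING, average_window,
                  build_fir_design, estimate_betas)
from .geometry import (enumerate_quartets, jackknife_group_angles,
                       participant_angles, participant_rdms, summarize_angles)
from .io import write_patterns, write_results
from .patterns import PatternDataset
from .stats import bh_adjust, cross_decoding_ratio, significance_stars, t_test
from .synth import GeometryParams, generate_dataset

WINDOWS = {w.name: w for w in (EXP1_DELAY, EXP2_DELAY, EXP2_ENCODING)}


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible end-to-end run."""

    seed: Optional[int] = None
    experiment: str = EXP1
    analysis: str = "exp1-cross-distractor"
    n_participants: int = 12
    n_vertices: int = 200
    theta_deg: float = 0.0
    target_amplitude: float = 1.9
    context_amplitude: float = 1.9
    order_amplitude: float = 0.95
    noise_sd: float = 1.0
    rho: float = 0.5
    use_timeseries: bool = False
    n_runs_per_split: int = 7
    window: Optional[str] = None  # defaults to the experiment's delay window
    save_patterns: bool = False
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.n_participants < 3:
            raise ValueError("need at least 3 participants for the jackknife")
        if self.window is None:
            self.window = "exp1-delay" if self.experiment == EXP1 else "exp2-delay"
        if self.window not in WINDOWS:
            raise ValueError(f"unknown window {self.window!r}")

    def geometry_params(self, seed: int) -> GeometryParams:
        return GeometryParams(
            n_vertices=self.n_vertices, theta_deg=self.theta_deg,
            target_amplitude=self.target_amplitude,
            context_amplitude=self.context_amplitude,
            order_amplitude=self.order_amplitude,
            noise_sd=self.noise_sd, rho=self.rho, seed=seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _participant_dataset(config: PipelineConfig, seed: int) -> PatternDataset:
    params = config.geometry_params(seed)
    if not config.use_timeseries:
        return generate_dataset(params, config.experiment).data
    ds = generate_dataset(params, config.experiment, timeseries=True,
                          n_runs_per_split=config.n_runs_per_split)
    fir = build_fir_design(ds.design)
    betas = estimate_betas(ds.timeseries, fir)
    return average_window(betas, WINDOWS[config.window],
                          experiment=config.experiment)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write result tables and return the manifest."""
    ss = np.random.SeedSequence(config.seed)
    p_seeds = [int(s.generate_state(1)[0] % (2**31))
               for s in ss.spawn(config.n_participants)]

    # --- simulate (and optionally estimate via the FIR GLM) ---
    datasets = [_participant_dataset(config, s) for s in p_seeds]

    # --- decode ---
    decode_rows = []
    ratio_rows = []
    for p, data in enumerate(datasets):
        table = run_analysis(data, config.analysis, seed=config.seed)
        table.insert(0, "participant", p)
        decode_rows.append(table)
        within = table.loc[table["mode"] == "within", "accuracy"].mean()
        cross_tab = table.loc[table["mode"] == "cross", "accuracy"]
        cross = cross_tab.mean() if len(cross_tab) else np.nan
        if np.isfinite(cross):
            r = cross_decoding_ratio(within, cross)
            ratio_rows.append((p, within, cross,
                               r.ratio if r.valid else np.nan, r.valid))
    decoding = pd.concat(decode_rows, ignore_index=True)
    ratios = pd.DataFrame(
        ratio_rows, columns=["participant", "within", "cross", "ratio", "valid"])

    # --- geometry ---
    quartets = enumerate_quartets(config.experiment, config.analysis) \
        if config.analysis != "exp2-order" else []
    tables: dict[str, pd.DataFrame] = {"decoding": decoding, "ratios": ratios}
    if quartets:
        rdms = participant_rdms(datasets, quartets, seed=config.seed)
        tables["angles_participant"] = participant_angles(rdms, quartets)
        jack = jackknife_group_angles(rdms, quartets)
        tables["angles_jackknife"] = jack
        tables["angles_summary"] = summarize_angles(jack)

    # --- stats ---
    stats_rows = []
    within_acc = decoding[decoding["mode"] == "within"] \
        .groupby("participant")["accuracy"].mean()
    tr = t_test(within_acc, 0.5, tails=1)
    stats_rows.append(("within_vs_chance", "decoding", tr.statistic, tr.df, tr.p))
    if (decoding["mode"] == "cross").any():
        cross_acc = decoding[decoding["mode"] == "cross"] \
            .groupby("participant")["accuracy"].mean()
        tr = t_test(cross_acc, 0.5, tails=1)
        stats_rows.append(("cross_vs_chance", "decoding", tr.statistic, tr.df, tr.p))
        tr = t_test(within_acc, cross_acc, paired=True, tails=1)
        stats_rows.append(("cross_drop", "decoding", tr.statistic, tr.df, tr.p))
        valid = ratios[ratios["valid"]]["ratio"].dropna()
        if len(valid) >= 2:
            tr = t_test(valid, 1.0, tails=2)
            stats_rows.append(("ratio_vs_one", "ratio", tr.statistic, tr.df, tr.p))
    stats = pd.DataFrame(stats_rows, columns=["test", "family", "statistic",
                                              "df", "p"])
    stats["p_adjusted"] = bh_adjust(stats["p"].to_numpy(), stats["family"])
    stats["stars"] = [significance_stars(p) for p in stats["p_adjusted"]]
    tables["stats"] = stats

    # --- write outputs + manifest ---
    science_cfg = {k: v for k, v in asdict(config).items()
                   if k not in ("out_dir", "save_patterns")}
    manifest = {
        "package": "vwmgeom",
        "version": __version__,
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(science_cfg, sort_keys=True).encode()).hexdigest(),
        "participant_seeds": p_seeds,
        "outputs": {},
    }
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        paths = write_results(tables, out_dir)
        if config.save_patterns:
            for p, data in enumerate(datasets):
                paths[f"patterns_p{p}"] = write_patterns(
                    data, out_dir / f"participant{p:02d}")[0]
        for name, path in paths.items():
            manifest["outputs"][name] = {
                "path": str(path),
                "sha256": hashlib.sha256(Path(path).read_bytes()).hexdigest(),
            }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["tables"] = tables
    return manifest
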