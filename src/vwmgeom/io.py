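"""Delimited-text I/O for pattern datasets and result tables.

A :class:`~vwmgeom.patterns.PatternDataset` is stored as two text
files sharing a base path:

* ``<base>.patterns.tsv`` — the estimate x vertex matrix, tab
  separated, one header row ``v0..v{n-1}``;
* ``<base>.meta.yaml`` — a structured sidecar with the experiment id
  and, per matrix row, the condition key, split id and estimate id,
  plus free-form provenance.

The round trip write -> read reproduces the dataset exactly (values
are serialized with full float precision).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .patterns import PatternDataset


def write_patterns(data: PatternDataset, base: str | os.PathLike) -> tuple[Path, Path]:
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    mat_path = base.with_suffix(".patterns.tsv")
    meta_path = base.with_suffix(".meta.yaml")
    cols = [f"v{i}" for i in range(data.n_vertices)]
    pd.DataFrame(data.patterns, columns=cols).to_csv(
        mat_path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "format": "vwmgeom-patterns-v1",
        "experiment": data.experiment,
        "n_rows": int(data.patterns.shape[0]),
        "n_vertices": int(data.n_vertices),
        "conditions": [str(c) for c in data.conditions],
        "splits": [int(s) for s in data.splits],
        "estimates": [int(e) for e in data.estimates],
        "meta": _plain(data.meta),
    }
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    return mat_path, meta_path


def read_patterns(base: str | os.PathLike) -> PatternDataset:
    base = Path(base)
    mat_path = base.with_suffix(".patterns.tsv")
    meta_path = base.with_suffix(".meta.yaml")
    for p in (mat_path, meta_path):
        if not p.exists():
            raise FileNotFoundError(f"missing pattern file {p}")
    meta = yaml.safe_load(meta_path.read_text())
    if not isinstance(meta, dict) or meta.get("format") != "vwmgeom-patterns-v1":
        raise ValueError(f"{meta_path}: not a vwmgeom pattern sidecar")
    df = pd.read_csv(mat_path, sep="\t", float_precision="round_trip")
    for field in ("conditions", "splits", "estimates", "experiment"):
        if field not in meta:
            raise ValueError(f"{meta_path}: missing field {field!r}")
    n = len(df)
    for field in ("conditions", "splits", "estimates"):
        if len(meta[field]) != n:
            raise ValueError(
                f"{meta_path}: {field} lists {len(meta[field])} rows but the "
                f"matrix {mat_path} has {n}")
    if len(df.columns) != meta.get("n_vertices", len(df.columns)):
        raise ValueError(f"{mat_path}: vertex count does not match sidecar")
    return PatternDataset(
        patterns=df.to_numpy(dtype=float),
        conditions=np.asarray(meta["conditions"], dtype=object),
        splits=np.asarray(meta["splits"], dtype=int),
        estimates=np.asarray(meta["estimates"], dtype=int),
        experiment=meta["experiment"],
        meta=meta.get("meta", {}) or {},
    )


def write_results(tables: Mapping[str, pd.DataFrame],
                  out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write each result table as ``<name>.tsv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in tables.items():
        p = out_dir / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False, float_format="%.17g")
        paths[name] = p
    return paths


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
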