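"""Export of experiment results to plain-text tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .protocol import ExperimentResult
from .readout import aggregate

__all__ = ["write_result", "patterns_table", "summary_table"]


def write_result(result: ExperimentResult, out_dir: str | Path) -> dict[str, Path]:
    """Write freezing.csv, weights_summary.csv and run_meta.json.

    ``freezing.csv`` holds one row per (simulation, session, probe);
    ``weights_summary.csv`` one row per (simulation, session,
    pre_cluster, post_cluster); ``run_meta.json`` the full parameter and
    seed record plus any failed replicates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "freezing": out_dir / "freezing.csv",
        "weights": out_dir / "weights_summary.csv",
        "meta": out_dir / "run_meta.json",
    }
    result.freezing.to_csv(paths["freezing"], index=False)
    result.cluster_weights.to_csv(paths["weights"], index=False)
    spec = dataclasses.asdict(result.spec)
    meta = {
        "spec": spec,
        "simulation_spawn_keys": result.simulation_seeds,
        "failures": result.failures,
        "n_completed": int(result.freezing["simulation"].nunique())
        if not result.freezing.empty
        else 0,
    }
    paths["meta"].write_text(json.dumps(meta, indent=2, default=str))
    return paths


def patterns_table(layout, cues) -> pd.DataFrame:
    """Tidy (neuron, cluster, cue label, input) table for inspection/plots."""
    cluster_of = {}
    for name, idx in {**layout.named_clusters(), "background": layout.background}.items():
        for i in idx:
            cluster_of[int(i)] = name
    rows = []
    for cue in cues:
        for i, value in enumerate(cue.I):
            rows.append(
                {
                    "neuron": i,
                    "cluster": cluster_of[i],
                    "cue": cue.label,
                    "input": float(value),
                }
            )
    return pd.DataFrame(rows)


def summary_table(result: ExperimentResult) -> pd.DataFrame:
    """Across-simulation mean ± SEM freezing per session and probe."""
    return aggregate(result.freezing)
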