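#!/usr/bin/env python
"""Hebbian-plasticity blockade (S = 0) during reactivation sessions.

Models a protein-synthesis-like blockade of Hebbian learning in every
reexposure group, including the reconsolidation cue (shock/non-shock
inputs +3.80/-3.80, an intermediate representation close to the original
shock pattern).  Predictions checked: extinction (no-footshock) is
abolished because it is new learning; deconditioning-update shows a
*larger* drop after the first reactivation (degradation acts unopposed)
but worse long-run extinction.

Writes results/hebbian_block_freezing.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from decondnet import ExperimentSpec, aggregate, run_experiment

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--n-sims", type=int, default=100)
    parser.add_argument("--seed", type=int, default=2024)
    args = parser.parse_args()

    frames = []
    for group in ("no_footshock", "footshock", "reconsolidation"):
        for drug in ("vehicle", "hebbian_block"):
            res = run_experiment(
                ExperimentSpec(group=group, drug=drug,
                               n_simulations=args.n_sims, master_seed=args.seed)
            )
            frames.append(res.freezing)
    summary = aggregate(pd.concat(frames, ignore_index=True))
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "hebbian_block_freezing.csv", index=False)

    tone = summary[summary["probe"] == "tone_retrieval"]
    piv = tone[tone["session"].str.startswith("reactivation")].pivot(
        index=["group", "drug"], columns="session", values="mean"
    )
    print("tone-retrieval freezing across reactivation days (%):")
    print(piv.round(1).to_string())
    print(f"\nwrote {OUT / 'hebbian_block_freezing.csv'}")


if __name__ == "__main__":
    main()
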