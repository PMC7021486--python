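#!/usr/bin/env python
"""Multi-session extinction vs deconditioning-update under vehicle.

Runs both reexposure groups (no-footshock = pure extinction cue,
footshock = weak-shock deconditioning cue) for 100 replicate
simulations, then reports:

* tone-retrieval and session-end freezing across the four reactivation
  days plus test and renewal (the freezing-trajectory readout),
* the renewal contrast (training-context probe after reexposure),
* the cluster-mean weight signature: deconditioning weakens the
  conditioning-context<->shock and shock<->shock weights that extinction
  spares.

Writes results/extinction_freezing.csv and results/extinction_weights.csv.
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

    runs = {
        group: run_experiment(
            ExperimentSpec(group=group, drug="vehicle",
                           n_simulations=args.n_sims, master_seed=args.seed)
        )
        for group in ("no_footshock", "footshock")
    }

    freezing = pd.concat([r.freezing for r in runs.values()], ignore_index=True)
    weights = pd.concat([r.cluster_weights for r in runs.values()], ignore_index=True)
    summary = aggregate(freezing)
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "extinction_freezing.csv", index=False)
    weight_summary = (
        weights.groupby(["group", "session", "pre_cluster", "post_cluster"],
                        sort=False)["mean_weight"].mean().reset_index()
    )
    weight_summary.to_csv(OUT / "extinction_weights.csv", index=False)

    tone = summary[summary["probe"] == "tone_retrieval"].pivot(
        index="session", columns="group", values="mean"
    )
    print("mean tone-retrieval freezing (%), n =", args.n_sims, "simulations:")
    print(tone.round(1).to_string())

    for group, res in runs.items():
        print(f"\n{group}: renewal freezing {res.mean_freezing('renewal'):.1f}%")
        for pair in (("context_a", "shock"), ("shock", "shock")):
            before = 0.5 * (res.mean_cluster_weight("training", *pair)
                            + res.mean_cluster_weight("training", *pair[::-1]))
            after = 0.5 * (res.mean_cluster_weight("reactivation_4", *pair)
                           + res.mean_cluster_weight("reactivation_4", *pair[::-1]))
            print(f"  {pair[0]}<->{pair[1]} mean weight: "
                  f"post-training {before:.2f} -> post-reexposure {after:.2f}")
    print(f"\nwrote {OUT / 'extinction_freezing.csv'} and {OUT / 'extinction_weights.csv'}")


if __name__ == "__main__":
    main()
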