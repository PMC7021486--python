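#!/usr/bin/env python
"""Virtual nimodipine: mismatch-induced degradation knocked out (D = 0).

L-type calcium-channel blockade before each reactivation is modeled by
setting the degradation factor D to 0 in reactivation sessions.  The
prediction this driver checks: the knockout abolishes deconditioning-
update (the weak-footshock group keeps freezing) while leaving
no-footshock extinction, which rests on Hebbian new learning, intact.

Writes results/nimodipine_freezing.csv.
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
    for group in ("no_footshock", "footshock"):
        for drug in ("vehicle", "nimodipine"):
            res = run_experiment(
                ExperimentSpec(group=group, drug=drug,
                               n_simulations=args.n_sims, master_seed=args.seed)
            )
            frames.append(res.freezing)
    summary = aggregate(pd.concat(frames, ignore_index=True))
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "nimodipine_freezing.csv", index=False)

    tone = summary[summary["probe"] == "tone_retrieval"]
    days = tone[tone["session"].isin(["reactivation_1", "reactivation_4"])]
    piv = days.pivot(index=["group", "drug"], columns="session", values="mean")
    piv["decline"] = piv["reactivation_1"] - piv["reactivation_4"]
    print("tone-retrieval freezing, day 1 vs day 4 (%):")
    print(piv.round(1).to_string())
    print(f"\nwrote {OUT / 'nimodipine_freezing.csv'}")


if __name__ == "__main__":
    main()
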