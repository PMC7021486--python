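#!/usr/bin/env python
"""Export the cluster layout and every cue pattern the protocols use.

Writes results/cue_patterns.csv (one row per neuron x cue) and prints
the cluster composition of each cue, for eyeballing the virtual
conditioning/reexposure/retrieval inputs.
"""

from pathlib import Path

from decondnet import (
    background_pattern,
    make_layout,
    reexposure_pattern,
    retrieval_cue,
    training_pattern,
)
from decondnet.io import patterns_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    layout = make_layout()
    cues = [
        background_pattern(layout),
        training_pattern(layout),
        reexposure_pattern(layout, "no_footshock"),
        reexposure_pattern(layout, "footshock"),
        reexposure_pattern(layout, "reconsolidation"),
        retrieval_cue(layout, "B"),
        retrieval_cue(layout, "A"),
    ]
    table = patterns_table(layout, cues)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "cue_patterns.csv", index=False)

    summary = table.pivot_table(index="cluster", columns="cue", values="input",
                                aggfunc="mean")
    print("mean cue input per cluster (rows: cluster, columns: cue):")
    print(summary.round(2).to_string())
    print(f"\nwrote {OUT / 'cue_patterns.csv'} ({len(table)} rows)")


if __name__ == "__main__":
    main()
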