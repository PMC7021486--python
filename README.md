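# decondnet

Attractor-network simulations of fear-memory updating: why pairing a
reminder cue with a *much weaker* aversive stimulus ("deconditioning-
update") can erase a fear memory more thoroughly than ordinary
extinction, and why the two procedures dissociate pharmacologically.

The package is for computational and behavioral neuroscientists who
want a compact, fully reproducible implementation of the
Hopfield-style memory model behind that account: virtual
fear-conditioning protocols (training, spaced reexposure with or
without a weak footshock, test, renewal) run on a 100-neuron
continuous-activity network, with drug manipulations modeled as
parameter knockouts.

## The model

Neuron activities `u_i ∈ (0, 1)` in a fully connected network relax to

    τ du_i/dt = −u_i + ½ [1 + tanh( Σ_j w_ij u_j + I_i )]

under a cue `I` (`w_ij`: connection onto postsynaptic `i` from
presynaptic `j`; `τ = 1`).  At the end of each learning session the
settled state `u` updates the weights once:

    ΔW = −γ W + S uᵀu − S (1−u)ᵀu + D (I_norm − u)ᵀ u

The first two outer products are Hebbian learning (HLP; strengthen
co-active pairs, inhibit connections onto silent postsynaptic neurons
from active presynaptic ones).  The last is mismatch-induced
degradation (MID): when a cue retrieves an attractor that differs from
what the cue itself dictates (`I_norm = ½(1+tanh I)`, the cue mapped
through the network's own gain function), the mismatch `m = I_norm − u`
updates the responsible weights — the model's analogue of
reconsolidation-like destabilization.  Defaults: `γ = 0`, `S = 0.8`
(training) or `0.25` (reactivation), `D = 0.95`; virtual nimodipine
sets `D = 0`, Hebbian blockade sets `S = 0`.

Non-overlapping clusters represent context A (6 neurons), context B
(6), tone (2), shock (10), non-shock (10) and background (66).
Freezing is read out from a settled state as
`100 · Σ_shock u / (Σ_shock u + Σ_non-shock u)`; each session's value is
the mean over 100 retrieval trials with noisy initial activity, and
experiments are replicated over 100 independently seeded simulations.

## Worked example

```python
from decondnet import ExperimentSpec, run_experiment

res = run_experiment(ExperimentSpec(group="footshock", drug="vehicle",
                                    n_simulations=100, master_seed=2024))
for day in (1, 2, 3, 4):
    print(day, round(res.mean_freezing(f"reactivation_{day}"), 1))
print("renewal", round(res.mean_freezing("renewal"), 1))
```

prints

```
1 100.0
2 97.8
3 0.0
4 0.0
renewal 0.0
```

— the weak-footshock (deconditioning) group starts fully afraid, keeps
retrieving the original fear attractor on the first days (which lets
MID degrade it), and collapses to 0% freezing by day 3 with no renewal
when probed in the training context.  The same run with
`group="no_footshock"` extinguishes only on day 4 and renews at ~39%,
because extinction builds a new attractor and spares the shock memory's
weights.  The numbered scripts under `analysis/` reproduce the full
set of conditions and write tidy CSVs to `results/`:

```sh
python analysis/01_cue_patterns.py
python analysis/02_deconditioning_vs_extinction.py
python analysis/03_degradation_blockade.py
python analysis/04_hebbian_blockade.py
```

A CLI wraps single runs: `decondnet run --group footshock --drug
nimodipine --n-sims 100 --seed 1 --out scratch/run1` writes
`freezing.csv`, `weights_summary.csv` and `run_meta.json`.

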