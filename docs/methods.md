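# Methods

## Model

The memory substrate is a fully connected network of `N = 100` rate
neurons with continuous activities `u_i`.  Given weights `W = (w_ij)`
(`i` postsynaptic, `j` presynaptic) and a cue `I`, activity follows

    τ du_i/dt = −u_i + ½ [1 + tanh( Σ_j w_ij u_j + I_i )],   τ = 1.

Fixed points satisfy `u = ½(1 + tanh(Wu + I))` and lie strictly inside
(0, 1); stored memories are attractors of this flow and retrieval is
relaxation from a noisy initial state.  Self-connections are retained:
the network is fully connected and the outer-product learning rules
generate diagonal terms naturally.

At the end of each learning session the settled state under the full
learning cue produces one weight update

    ΔW = −γ W + HLP + MID,
    HLP = S uᵀu − S (1−u)ᵀu,
    MID = D (I_norm − u)ᵀ u,

with `γ = 0` throughout (no passive decay), `S = 0.8` in the two
encoding sessions and `S = 0.25` in reactivation sessions (weaker
stimuli), and `D = 0.95` everywhere except under virtual nimodipine
(`D = 0` in reactivations).  A constant `s0 = 1` is recorded with the
other model parameters for provenance but enters no equation.

### Cue normalization (a genuinely open design point)

The mismatch vector `m = I_norm − u` needs a cue normalized into the
activity range; the normalization is otherwise unconstrained.  Two
candidates were implemented (`normalize_cue(..., method=...)`):

* **sigmoid** (default): `I_norm = ½(1 + tanh I)` — the network's own
  gain function applied to the cue, i.e. the steady state the cue alone
  would impose on an unconnected network (identical to the `W = 0`
  fixed point of the dynamics).  Saturating inputs (±5) map to ≈0/1,
  and the weak-footshock input −2.31 still dictates an essentially
  silent shock cluster (0.010).
* **affine**: `I_norm = (I + 5)/10`, a linear rescaling of the
  admissible input range (−2.31 ↦ 0.269).

The affine variant makes MID target a *partially active* shock cluster
(0.269), which arithmetically cancels the Hebbian inhibition that
accumulates onto shock neurons (−S per session vs +D·(0.269−u)·u), so
the deconditioning group never extinguishes and none of the group/drug
dissociations emerge.  Under the sigmoid variant the full
phenomenology appears, including the fine-grained prediction that
Hebbian blockade during deconditioning produces a *larger* drop after
the first reactivation but worse long-run extinction.  The sigmoid
normalization is therefore the package default; it is also the more
principled reading, since it compares like with like (what the cue
would impose vs what the network retrieved, both expressed as
activities).

## Patterns and protocols

Contiguous index blocks form the clusters (context A: 0–5, context B:
6–11, tone: 12–13, shock: 14–23, non-shock: 24–33, background: 34–99);
contiguity makes the cluster-resolved weight matrices directly
readable.  Learning cues drive neurons at ±5 except the group-specific
shock/non-shock inputs during reexposure: (−5, +5) for the pure
extinction cue, (−2.31, +2.31) for deconditioning, (+3.80, −3.80) for
the reconsolidation cue (intermediate representations between the
training and extinction patterns).  Retrieval probes drive context +
tone neurons at 1.5 and everything else at 0.  The pre-existing
"background" memory excites a fixed 10-neuron block of the background
cluster, matched in size to the shock cluster so its attractor has a
comparable basin; its content is otherwise arbitrary and disjoint from
every task cluster.

Each experiment runs, per simulation: background encoding, fear
training, `k = 4` reactivation sessions, then test (context-B probe)
and renewal (context-A probe).  Within a session the retrieval battery
runs first (100 trials, weights frozen), then — in learning sessions —
the network settles under the full learning cue, the freezing of that
state is recorded as the session-end readout, and the single weight
update is applied.  Test and renewal are pure readouts.  Drug
knockouts apply to reactivation sessions only.

## Stochasticity and seeding

Initial weights are i.i.d. uniform on [−0.05, 0.05] (drawn once per
simulation); initial activities for every settling — each retrieval
trial and each session-end — are i.i.d. uniform on [0, 0.1].  The
stated noise intervals are read as uniform distributions: an interval
fully characterizes a uniform, and a bounded interval is what keeps
initial activities inside the valid range.  Per-trial redraws are what
make a 100-trial battery informative as a percentage.  The master seed
spawns one independent child stream per simulation
(`numpy.random.SeedSequence.spawn`), and draws within a simulation are
consumed in a fixed documented order, so results are bit-reproducible
and invariant to replication count and execution order.

## Numerics

Settling uses forward Euler with `dt = 0.1·τ` and stops when every
component of `−u + ½(1+tanh(drive))` is below 1e−6 in magnitude
(cap 10,000 steps; exceeding it raises a "did not settle" signal
carrying the last state, and the experiment runner logs such replicates
as incomplete instead of aborting the run).  Halving `dt` moves settled
states by far less than the tolerance (property-tested).  Activities
are not clipped during integration; only fixed points are interpreted.
A retrieval battery settles all 100 trial initial conditions as one
`(N, trials)` batch against the shared weights — mathematically
identical to per-trial settling (each column evolves independently) and
roughly two orders of magnitude faster, which is what keeps a
100-simulation experiment near ten seconds of CPU.

## Readouts

Freezing of a settled state is the shock cluster's share of shock +
non-shock activity, as a percentage; session freezing averages the 100
trials, and condition summaries report mean ± SEM over the 100
simulations.  Cluster-mean weight matrices average `w_ij` over all
(postsynaptic ∈ Q, presynaptic ∈ P) pairs for each ordered cluster
pair, including diagonal blocks (self-connections included,
consistently with the dynamics).  The across-simulation mean matrix is
reported.

## What the generator does and does not emulate

All inputs are synthetic by design — the study object is the model
itself, so the cue patterns, noise and protocols *are* the data.  The
representation is deliberately reductionist: clusters are
non-overlapping and localist, cues have one-to-one topology onto
neurons, time within and between sessions is not modeled (massed vs
spaced protocols are indistinguishable), and there is a single
background memory.  Passing tests therefore show that the *mechanism*
(attractor retrieval gating mismatch-degradation vs new learning)
produces the observed dissociations — not that the parameters are
biologically calibrated, nor anything about spiking dynamics, synaptic
bounds, or overlapping distributed codes.

## Known limitations

* Freezing percentages saturate near 0/100 with small SEMs; the model
  reproduces orderings and dissociations, not graded behavioral values.
* The weight-level dissociation between extinction and deconditioning
  lives in the shock-memory weights (conditioning-context ↔ shock and
  shock ↔ shock): those are untouched by extinction and collapse under
  deconditioning.  Blocks from active presynaptic clusters onto silent
  postsynaptic ones (e.g. tone → shock) acquire Hebbian inhibition in
  *both* procedures — that is intrinsic to the heterosynaptic term of
  HLP.
* Reconsolidation-cue reexposure (+3.80) retrieves and re-stabilizes
  the fear attractor (freezing stays at 100%); modeling drug effects on
  that restabilization beyond the S/D knockouts is out of scope.
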