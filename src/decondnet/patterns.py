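"""Cluster layout, cue patterns and stochastic initial conditions.

Every input the simulations consume is constructed here; no external
data is needed.  Non-overlapping clusters of the 100-neuron network
stand for the conditioning context (A), the extinction context (B), the
tone, the aversive footshock, the absence of shock (safety), and
task-unrelated background neurons:

====================  =======  ==============
cluster               size     indices (0-based)
====================  =======  ==============
context A             6        0-5
context B             6        6-11
tone                  2        12-13
shock                 10       14-23
non-shock             10       24-33
background            66       34-99
====================  =======  ==============

Learning cues drive each neuron at up to +/-5; retrieval cues probe with
1.5 on the targeted neurons and 0 elsewhere.  The deconditioning
(weak-footshock) reexposure drives the shock/non-shock clusters at
-/+2.31, the reconsolidation reexposure at +/-3.80 — intermediate
representations between the training and extinction patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "N_NEURONS",
    "EXCITE",
    "INHIBIT",
    "RETRIEVAL_INPUT",
    "REEXPOSURE_SHOCK_INPUTS",
    "ClusterLayout",
    "CuePattern",
    "make_layout",
    "training_pattern",
    "reexposure_pattern",
    "retrieval_cue",
    "background_pattern",
    "initial_weight_noise",
    "initial_activity_noise",
]

N_NEURONS = 100
EXCITE = 5.0
INHIBIT = -5.0
RETRIEVAL_INPUT = 1.5

#: (shock-cluster input, non-shock-cluster input) per reexposure group.
REEXPOSURE_SHOCK_INPUTS = {
    "no_footshock": (-5.0, 5.0),
    "footshock": (-2.31, 2.31),
    "reconsolidation": (3.80, -3.80),
}


@dataclass(frozen=True)
class ClusterLayout:
    """Named, pairwise-disjoint index sets partitioning the network."""

    context_a: np.ndarray
    context_b: np.ndarray
    tone: np.ndarray
    shock: np.ndarray
    non_shock: np.ndarray
    background: np.ndarray
    n: int = N_NEURONS

    def named_clusters(self) -> dict[str, np.ndarray]:
        """Task clusters in the canonical reporting order."""
        return {
            "context_a": self.context_a,
            "context_b": self.context_b,
            "tone": self.tone,
            "shock": self.shock,
            "non_shock": self.non_shock,
        }


@dataclass(frozen=True)
class CuePattern:
    """A length-N input vector with a protocol label."""

    I: np.ndarray
    label: str


def make_layout(n: int = N_NEURONS) -> ClusterLayout:
    """Contiguous block layout (deterministic; noise is seeded elsewhere)."""
    if n != N_NEURONS:
        raise ValueError("the cluster layout is defined for a 100-neuron network")
    idx = np.arange(n)
    return ClusterLayout(
        context_a=idx[0:6],
        context_b=idx[6:12],
        tone=idx[12:14],
        shock=idx[14:24],
        non_shock=idx[24:34],
        background=idx[34:100],
        n=n,
    )


def _cue(layout: ClusterLayout, base: float, label: str) -> np.ndarray:
    return np.full(layout.n, base, dtype=float)


def training_pattern(layout: ClusterLayout) -> CuePattern:
    """Fear acquisition: context A + tone + shock excited, all else inhibited."""
    I = _cue(layout, INHIBIT, "training")
    I[layout.context_a] = EXCITE
    I[layout.tone] = EXCITE
    I[layout.shock] = EXCITE
    return CuePattern(I=I, label="training")


def reexposure_pattern(layout: ClusterLayout, group: str) -> CuePattern:
    """Session-end learning cue for a reactivation session.

    All groups excite context B and tone and inhibit context A and
    background; the shock and non-shock clusters receive the
    group-specific inputs of :data:`REEXPOSURE_SHOCK_INPUTS`.
    """
    try:
        shock_in, non_shock_in = REEXPOSURE_SHOCK_INPUTS[group]
    except KeyError:
        raise ValueError(
            f"unknown group {group!r}; expected one of {sorted(REEXPOSURE_SHOCK_INPUTS)}"
        ) from None
    I = _cue(layout, INHIBIT, group)
    I[layout.context_b] = EXCITE
    I[layout.tone] = EXCITE
    I[layout.shock] = shock_in
    I[layout.non_shock] = non_shock_in
    return CuePattern(I=I, label=f"{group}_reexposure")


def retrieval_cue(layout: ClusterLayout, context: str) -> CuePattern:
    """Non-plastic probe: 1.5 on (context + tone) neurons, 0 elsewhere.

    ``context='B'`` is the standard test cue; ``context='A'`` probes
    renewal in the training context.
    """
    if context not in ("A", "B"):
        raise ValueError("context must be 'A' or 'B'")
    I = np.zeros(layout.n)
    ctx = layout.context_a if context == "A" else layout.context_b
    I[ctx] = RETRIEVAL_INPUT
    I[layout.tone] = RETRIEVAL_INPUT
    return CuePattern(I=I, label=f"retrieval_context_{context}")


def background_pattern(layout: ClusterLayout) -> CuePattern:
    """A pre-existing memory unrelated to fear conditioning.

    Excites a fixed 10-neuron block of the background cluster (matched
    in size to the shock cluster, disjoint from every task cluster) and
    inhibits the rest of the network.
    """
    I = _cue(layout, INHIBIT, "background")
    I[layout.background[:10]] = EXCITE
    return CuePattern(I=I, label="background")


def initial_weight_noise(n: int, rng: np.random.Generator | int) -> np.ndarray:
    """Initial synaptic weights: i.i.d. noise, uniform on [-0.05, 0.05]."""
    rng = np.random.default_rng(rng)
    return rng.uniform(-0.05, 0.05, size=(n, n))


def initial_activity_noise(
    n: int, rng: np.random.Generator | int, trials: int | None = None
) -> np.ndarray:
    """Start-of-settling activities: i.i.d. uniform on [0, 0.1].

    With ``trials`` set, returns an ``(n, trials)`` matrix of
    independent initial conditions (one column per retrieval trial).
    """
    rng = np.random.default_rng(rng)
    size = n if trials is None else (n, trials)
    return rng.uniform(0.0, 0.1, size=size)
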