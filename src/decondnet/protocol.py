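"""Virtual fear-conditioning experiments on the attractor network.

An experiment is a fixed session sequence run independently in many
seeded replicate simulations:

1. *background* — encode a memory unrelated to fear conditioning.
2. *training* — encode the fear memory (context A + tone + shock).
3. *reactivation 1..k* — daily reexposure sessions.  The retrieval
   battery (freezing probe) runs first; at session end the network
   settles under the group's full reexposure cue and the weights receive
   one plasticity update.
4. *test* — retrieval battery with the context-B + tone cue, no learning.
5. *renewal* — retrieval battery with the context-A + tone cue.

Each session's freezing percentage is the mean over ``n_retrieval_trials``
independent retrieval trials (fresh initial-activity noise per trial,
weights frozen throughout the battery).  Pharmacological manipulations
are parameter knockouts applied to reactivation sessions only:
nimodipine (L-type calcium-channel blockade) sets the mismatch
degradation factor D to 0; Hebbian blockade (e.g. protein-synthesis
inhibition) sets S to 0.

Randomness: the master seed spawns one independent child stream per
simulation.  Within a simulation, draws are consumed in a fixed order —
initial weight noise once, then per session one ``(N, trials)`` block of
retrieval-trial activity noise followed, in learning sessions, by one
length-``N`` session-end activity draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .network import DidNotSettleError, DynamicsParams, settle
from .patterns import (
    ClusterLayout,
    CuePattern,
    background_pattern,
    initial_activity_noise,
    initial_weight_noise,
    make_layout,
    reexposure_pattern,
    retrieval_cue,
    training_pattern,
)
from .plasticity import PlasticityParams, apply_update, normalize_cue
from .readout import cluster_weight_matrix, freezing

__all__ = [
    "TRAINING_PARAMS",
    "REACTIVATION_PARAMS",
    "GROUPS",
    "DRUGS",
    "SessionSpec",
    "ExperimentSpec",
    "ExperimentResult",
    "apply_drug",
    "run_session",
    "run_experiment",
]

#: Learning-session plasticity: strong Hebbian factor during encoding.
TRAINING_PARAMS = PlasticityParams(S=0.8, D=0.95, gamma=0.0)
#: Reactivation-session plasticity: weaker stimuli, hence smaller S.
REACTIVATION_PARAMS = PlasticityParams(S=0.25, D=0.95, gamma=0.0)

GROUPS = ("no_footshock", "footshock", "reconsolidation")
DRUGS = ("vehicle", "nimodipine", "hebbian_block")


def apply_drug(params: PlasticityParams, drug: str) -> PlasticityParams:
    """Model a drug given before reactivation as a parameter knockout."""
    if drug == "vehicle":
        return params
    if drug == "nimodipine":
        return replace(params, D=0.0)
    if drug == "hebbian_block":
        return replace(params, S=0.0)
    raise ValueError(f"unknown drug {drug!r}; expected one of {DRUGS}")


@dataclass(frozen=True)
class SessionSpec:
    """One session of a protocol.

    ``kind`` is one of train / reactivation / test / renewal; learning
    sessions (train, reactivation) carry a learning cue and plasticity
    parameters, pure readout sessions (test, renewal) carry neither.
    """

    kind: str
    label: str
    retrieval_cue: CuePattern
    learning_cue: Optional[CuePattern] = None
    plasticity: Optional[PlasticityParams] = None
    n_retrieval_trials: int = 100

    def __post_init__(self) -> None:
        if self.kind in ("train", "reactivation"):
            if self.learning_cue is None or self.plasticity is None:
                raise ValueError(f"{self.kind} session requires a learning cue and params")
        elif self.kind in ("test", "renewal"):
            if self.learning_cue is not None:
                raise ValueError(f"{self.kind} session is a pure readout; no learning cue")
        else:
            raise ValueError(f"unknown session kind {self.kind!r}")
        if self.n_retrieval_trials < 1:
            raise ValueError("n_retrieval_trials must be >= 1")


@dataclass(frozen=True)
class ExperimentSpec:
    """A full virtual experiment: group, drug, replication and seeding."""

    group: str = "footshock"
    drug: str = "vehicle"
    n_reactivation_sessions: int = 4
    n_simulations: int = 100
    n_retrieval_trials: int = 100
    master_seed: int = 0
    training_params: PlasticityParams = TRAINING_PARAMS
    reactivation_params: PlasticityParams = REACTIVATION_PARAMS
    dynamics: DynamicsParams = DynamicsParams()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}; expected one of {DRUGS}")

    def sessions(self, layout: ClusterLayout) -> list[SessionSpec]:
        """The session sequence this spec prescribes."""
        test_cue = retrieval_cue(layout, "B")
        renewal_cue = retrieval_cue(layout, "A")
        reactivation = apply_drug(self.reactivation_params, self.drug)
        out = [
            SessionSpec(
                kind="train",
                label="background",
                retrieval_cue=test_cue,
                learning_cue=background_pattern(layout),
                plasticity=self.training_params,
                n_retrieval_trials=self.n_retrieval_trials,
            ),
            SessionSpec(
                kind="train",
                label="training",
                retrieval_cue=test_cue,
                learning_cue=training_pattern(layout),
                plasticity=self.training_params,
                n_retrieval_trials=self.n_retrieval_trials,
            ),
        ]
        for day in range(1, self.n_reactivation_sessions + 1):
            out.append(
                SessionSpec(
                    kind="reactivation",
                    label=f"reactivation_{day}",
                    retrieval_cue=test_cue,
                    learning_cue=reexposure_pattern(layout, self.group),
                    plasticity=reactivation,
                    n_retrieval_trials=self.n_retrieval_trials,
                )
            )
        out.append(
            SessionSpec(
                kind="test",
                label="test",
                retrieval_cue=test_cue,
                n_retrieval_trials=self.n_retrieval_trials,
            )
        )
        out.append(
            SessionSpec(
                kind="renewal",
                label="renewal",
                retrieval_cue=renewal_cue,
                n_retrieval_trials=self.n_retrieval_trials,
            )
        )
        return out


@dataclass
class ExperimentResult:
    """Tidy per-simulation records plus the full parameter provenance.

    ``freezing`` has one row per (simulation, session, probe) with the
    freezing percentage; ``cluster_weights`` one row per (simulation,
    session, pre_cluster, post_cluster) with the post-session mean
    weight.  ``failures`` lists simulations aborted by non-convergence,
    with their seeds, so incomplete replicates are visible.
    """

    spec: ExperimentSpec
    freezing: pd.DataFrame
    cluster_weights: pd.DataFrame
    simulation_seeds: list[int]
    failures: list[dict] = field(default_factory=list)

    def mean_freezing(self, session: str, probe: str = "tone_retrieval") -> float:
        """Across-simulation mean freezing for one session/probe cell."""
        mask = (self.freezing["session"] == session) & (self.freezing["probe"] == probe)
        if not mask.any():
            raise KeyError(f"no records for session={session!r}, probe={probe!r}")
        return float(self.freezing.loc[mask, "freezing_pct"].mean())

    def mean_cluster_weight(self, session: str, pre: str, post: str) -> float:
        """Across-simulation mean of one cluster-pair weight after a session."""
        cw = self.cluster_weights
        mask = (
            (cw["session"] == session)
            & (cw["pre_cluster"] == pre)
            & (cw["post_cluster"] == post)
        )
        if not mask.any():
            raise KeyError(f"no weights for session={session!r}, {pre!r}->{post!r}")
        return float(cw.loc[mask, "mean_weight"].mean())


def run_session(
    weights: np.ndarray,
    spec: SessionSpec,
    layout: ClusterLayout,
    rng: np.random.Generator,
    dynamics: DynamicsParams = DynamicsParams(),
) -> tuple[np.ndarray, dict]:
    """Run one session: retrieval battery, then (optionally) learning.

    The battery settles ``n_retrieval_trials`` independent noisy initial
    states in parallel under the frozen weights and the retrieval cue
    and records mean freezing.  In learning sessions the network then
    settles under the full learning cue from fresh noise; the freezing
    of that settled state is the session-end readout, and the weights
    receive one plasticity update against the cue's normalized form.

    Returns the (possibly updated) weights and a record dict with the
    freezing readouts and the post-session cluster-mean weight matrix.
    """
    n = layout.n
    u0 = initial_activity_noise(n, rng, trials=spec.n_retrieval_trials)
    try:
        settled = settle(u0, weights, spec.retrieval_cue.I, dynamics)
    except DidNotSettleError as err:
        err.args = (f"session {spec.label!r}: {err.args[0]}",)
        raise
    trial_freezing = np.array(
        [freezing(settled[:, t], layout) for t in range(spec.n_retrieval_trials)]
    )
    record = {
        "label": spec.label,
        "kind": spec.kind,
        "tone_freezing": float(trial_freezing.mean()),
        "trial_freezing": trial_freezing,
        "session_end_freezing": None,
    }
    new_weights = weights
    if spec.learning_cue is not None:
        u_end = settle(
            initial_activity_noise(n, rng), weights, spec.learning_cue.I, dynamics
        )
        record["session_end_freezing"] = freezing(u_end, layout)
        i_norm = normalize_cue(spec.learning_cue.I)
        new_weights = apply_update(weights, u_end, i_norm, spec.plasticity)
    record["cluster_weights"] = cluster_weight_matrix(new_weights, layout)
    return new_weights, record


def _run_simulation(
    sim_index: int,
    seed_seq: np.random.SeedSequence,
    spec: ExperimentSpec,
    layout: ClusterLayout,
) -> list[dict]:
    rng = np.random.default_rng(seed_seq)
    weights = initial_weight_noise(layout.n, rng)
    records = []
    for session in spec.sessions(layout):
        weights, record = run_session(weights, session, layout, rng, spec.dynamics)
        record["simulation"] = sim_index
        records.append(record)
    return records


def run_experiment(spec: ExperimentSpec, layout: ClusterLayout | None = None) -> ExperimentResult:
    """Run all replicate simulations of one experiment.

    Simulations are mutually independent (each consumes its own child
    seed stream), so results are invariant to execution order.  A
    simulation whose dynamics fail to settle is dropped and logged in
    ``failures`` rather than aborting the whole experiment.
    """
    layout = layout or make_layout()
    children = np.random.SeedSequence(spec.master_seed).spawn(spec.n_simulations)
    freezing_rows: list[dict] = []
    weight_rows: list[dict] = []
    failures: list[dict] = []
    for sim, child in enumerate(children):
        try:
            records = _run_simulation(sim, child, spec, layout)
        except DidNotSettleError as err:
            failures.append(
                {"simulation": sim, "seed": child.entropy, "error": str(err)}
            )
            continue
        for rec in records:
            freezing_rows.append(
                {
                    "simulation": sim,
                    "session": rec["label"],
                    "probe": "tone_retrieval",
                    "freezing_pct": rec["tone_freezing"],
                }
            )
            if rec["session_end_freezing"] is not None:
                freezing_rows.append(
                    {
                        "simulation": sim,
                        "session": rec["label"],
                        "probe": "session_end",
                        "freezing_pct": rec["session_end_freezing"],
                    }
                )
            cw = rec["cluster_weights"].stack()
            for (pre, post), value in cw.items():
                weight_rows.append(
                    {
                        "simulation": sim,
                        "session": rec["label"],
                        "pre_cluster": pre,
                        "post_cluster": post,
                        "mean_weight": float(value),
                    }
                )
    freezing_df = pd.DataFrame(freezing_rows)
    weights_df = pd.DataFrame(weight_rows)
    for df in (freezing_df, weights_df):
        df.insert(0, "group", spec.group)
        df.insert(1, "drug", spec.drug)
    return ExperimentResult(
        spec=spec,
        freezing=freezing_df,
        cluster_weights=weights_df,
        simulation_seeds=[int(c.spawn_key[0]) for c in children],
        failures=failures,
    )
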