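"""Session-end synaptic plasticity: Hebbian learning and mismatch-induced degradation.

After the network settles to a state ``u`` under a learning cue ``I``,
the weight matrix receives a single update

    dW = -gamma * W + HLP + MID

built from two independent rules:

* ``HLP = S u^T u - S (1 - u)^T u`` — Hebbian learning plasticity.
  Entry (i, j) is ``S u_i u_j - S (1 - u_i) u_j`` with i postsynaptic:
  co-active pairs are strengthened, and connections onto a silent
  postsynaptic neuron from an active presynaptic one are driven
  inhibitory. ``S`` collects the biological requirements for Hebbian
  plasticity (protein synthesis, receptor activation, ...).
* ``MID = D m^T u`` with mismatch vector ``m = I_norm - u`` — entry
  (i, j) is ``D (I_norm_i - u_i) u_j``. When a cue retrieves a stored
  attractor that differs from the cue itself, the mismatch updates the
  connections responsible, the model's analogue of reconsolidation-like
  destabilization. ``D`` collects the requirements for destabilization
  (protein degradation, L-type voltage-gated calcium channels).

``I_norm`` maps the raw cue (inputs in ``[-amplitude, +amplitude]``)
affinely onto ``[0, 1]`` so that it is commensurable with activities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CUE_AMPLITUDE",
    "PlasticityParams",
    "normalize_cue",
    "hebbian_term",
    "mismatch_term",
    "apply_update",
]

#: Full excitatory/inhibitory cue magnitude used during learning.
CUE_AMPLITUDE = 5.0


@dataclass(frozen=True)
class PlasticityParams:
    """Factors gating the two learning rules.

    ``S`` scales Hebbian plasticity, ``D`` scales mismatch-induced
    degradation, ``gamma`` is the passive synaptic decay (0 disables it,
    the default here).  ``s0`` is recorded for provenance with the other
    model constants but enters no update equation.
    """

    S: float
    D: float
    gamma: float = 0.0
    s0: float = 1.0

    def __post_init__(self) -> None:
        if self.S < 0 or self.D < 0:
            raise ValueError("S and D must be non-negative")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


def normalize_cue(
    cue: np.ndarray, amplitude: float = CUE_AMPLITUDE, method: str = "sigmoid"
) -> np.ndarray:
    """Map a raw cue onto [0, 1] so it is commensurable with activities.

    Two normalizations are provided:

    ``"sigmoid"`` (default)
        ``I_norm = 1/2 (1 + tanh(I))`` — the network's own gain
        function applied to the cue, i.e. the steady state the cue
        alone would impose on an unconnected network.  The mismatch
        ``m = I_norm - u`` then compares what the cue dictates with
        what the network actually retrieved.  Strong inputs saturate
        (|I| = 5 maps to ~0/1) and the weak-footshock input -2.31 still
        dictates an essentially silent shock cluster (0.01), so the
        degradation drive persists as long as the fear attractor is
        retrieved.  This is the normalization the protocol engine uses.
    ``"affine"``
        ``I_norm = (I + amplitude) / (2 amplitude)`` — linear rescaling
        of the admissible input range; -2.31 maps to 0.269.  Kept as a
        switchable alternative.

    Either way inputs must satisfy ``|I_i| <= amplitude``.
    """
    cue = np.asarray(cue, dtype=float)
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if np.any(np.abs(cue) > amplitude * (1 + 1e-12)):
        raise ValueError(f"cue exceeds amplitude {amplitude}")
    if method == "sigmoid":
        return 0.5 * (1.0 + np.tanh(cue))
    if method == "affine":
        return (cue + amplitude) / (2.0 * amplitude)
    raise ValueError(f"unknown normalization method {method!r}")


def hebbian_term(u: np.ndarray, S: float) -> np.ndarray:
    """Hebbian outer-product update ``S u^T u - S (1-u)^T u`` (row = postsynaptic)."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("activity state contains non-finite components")
    return S * np.outer(u, u) - S * np.outer(1.0 - u, u)


def mismatch_term(u: np.ndarray, i_norm: np.ndarray, D: float) -> np.ndarray:
    """Mismatch-induced degradation ``D (i_norm - u)^T u`` (row = postsynaptic)."""
    u = np.asarray(u, dtype=float)
    i_norm = np.asarray(i_norm, dtype=float)
    if u.shape != i_norm.shape:
        raise ValueError(f"dimension mismatch: u {u.shape} vs I_norm {i_norm.shape}")
    return D * np.outer(i_norm - u, u)


def apply_update(
    weights: np.ndarray,
    u: np.ndarray,
    i_norm: np.ndarray,
    params: PlasticityParams,
) -> np.ndarray:
    """One session-end weight update ``W + (-gamma W + HLP + MID)``.

    ``u`` is the state the network settled to under the learning cue and
    ``i_norm`` that cue's normalized form.  Returns a new matrix; the
    input is not modified.  With ``gamma = 0`` the update is purely
    accumulative.
    """
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    if weights.shape != (n, n) or len(u) != n:
        raise ValueError("weight/activity dimension mismatch")
    delta = (
        -params.gamma * weights
        + hebbian_term(u, params.S)
        + mismatch_term(u, i_norm, params.D)
    )
    return weights + delta
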