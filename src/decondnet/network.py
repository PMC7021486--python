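"""Continuous-activity attractor dynamics.

The network is a fully connected, Hopfield-like circuit of ``N`` rate
neurons whose activities ``u_i`` live in the unit interval.  Given a
synaptic weight matrix ``W`` (``w_ij`` is the connection *onto*
postsynaptic neuron ``i`` *from* presynaptic neuron ``j``) and a cue
input ``I``, each neuron relaxes according to

    tau * du_i/dt = -u_i + 1/2 * (1 + tanh( sum_j w_ij u_j + I_i ))

so that fixed points satisfy ``u_i = 1/2 (1 + tanh(drive_i))`` and are
strictly inside (0, 1).  Memories are attractors of this flow; retrieval
is relaxation to the attractor selected by the cue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DynamicsParams", "DidNotSettleError", "activation", "drive_sum", "settle"]


@dataclass(frozen=True)
class DynamicsParams:
    """Integration controls for :func:`settle`.

    Parameters
    ----------
    tau
        Neural time constant (dimensionless time units). Default 1.
    dt
        Forward-Euler step. Default ``0.1 * tau``.
    tol
        Convergence tolerance: the settle loop stops when every
        component of ``-u + activation(drive)`` (the rate of change per
        ``tau``) is below ``tol`` in magnitude.
    max_steps
        Iteration cap; exceeding it raises :class:`DidNotSettleError`.
    """

    tau: float = 1.0
    dt: float = 0.1
    tol: float = 1e-6
    max_steps: int = 10_000

    def __post_init__(self) -> None:
        if not (self.tau > 0 and self.dt > 0 and self.tol > 0):
            raise ValueError("tau, dt and tol must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


class DidNotSettleError(RuntimeError):
    """The flow failed to reach a fixed point within ``max_steps``.

    Carries the last state (``.state``) and the residual sup-norm
    (``.residual``) so callers can inspect or resume.
    """

    def __init__(self, state: np.ndarray, residual: float, steps: int):
        super().__init__(
            f"network did not settle after {steps} steps (residual {residual:.3g})"
        )
        self.state = state
        self.residual = residual
        self.steps = steps


def activation(x: np.ndarray) -> np.ndarray:
    """Sigmoid gain function ``1/2 (1 + tanh(x))``, with range (0, 1)."""
    return 0.5 * (1.0 + np.tanh(x))


def drive_sum(u: np.ndarray, weights: np.ndarray, cue: np.ndarray) -> np.ndarray:
    """Total input to each neuron: recurrent drive plus cue.

    Returns the length-``N`` vector (or ``(N, k)`` batch) with component
    ``i`` equal to ``sum_j w_ij u_j + I_i``; ``j`` indexes presynaptic
    neurons.
    """
    u = np.asarray(u, dtype=float)
    weights = np.asarray(weights, dtype=float)
    cue = np.asarray(cue, dtype=float)
    n = weights.shape[0]
    if weights.shape != (n, n) or u.shape[0] != n or cue.shape[0] != n:
        raise ValueError(
            f"dimension mismatch: W {weights.shape}, u {u.shape}, I {cue.shape}"
        )
    if u.ndim == 2 and cue.ndim == 1:
        return weights @ u + cue[:, None]
    return weights @ u + cue


def settle(
    state0: np.ndarray,
    weights: np.ndarray,
    cue: np.ndarray,
    params: DynamicsParams = DynamicsParams(),
) -> np.ndarray:
    """Relax the network to a steady state under a fixed cue.

    Integrates the rate equation by forward Euler from ``state0`` until
    the largest component of ``du/dt * tau`` drops below ``params.tol``.
    ``state0`` may be a length-``N`` vector or an ``(N, k)`` matrix of
    ``k`` independent initial conditions settled in parallel against the
    same weights and cue (the cue may also be ``(N, k)``).

    Returns the settled state with the same shape as ``state0``.

    Raises
    ------
    DidNotSettleError
        if convergence is not reached within ``max_steps``.
    ValueError
        on dimension mismatch or non-finite state/cue.
    """
    u = np.array(state0, dtype=float)
    weights = np.asarray(weights, dtype=float)
    cue = np.asarray(cue, dtype=float)
    if not np.all(np.isfinite(cue)):
        raise ValueError("cue contains non-finite components")
    step = params.dt / params.tau
    residual = np.inf
    for _ in range(params.max_steps):
        # residual = tau * du/dt; vanishes exactly at a fixed point
        residual_vec = activation(drive_sum(u, weights, cue)) - u
        residual = float(np.max(np.abs(residual_vec)))
        if not np.isfinite(residual):
            raise ValueError("network state became non-finite during integration")
        if residual < params.tol:
            return u
        u += step * residual_vec
    raise DidNotSettleError(u, residual, params.max_steps)
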