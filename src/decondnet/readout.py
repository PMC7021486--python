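"""Freezing quantification, cluster-mean weight matrices and aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .patterns import ClusterLayout

__all__ = ["CLUSTER_ORDER", "freezing", "cluster_weight_matrix", "aggregate"]

#: Reporting order for the five task clusters.
CLUSTER_ORDER = ("context_a", "context_b", "tone", "shock", "non_shock")


def freezing(u: np.ndarray, layout: ClusterLayout) -> float:
    """Freezing percentage read out from a settled network state.

    The model's fear index: the shock cluster's share of the total
    shock + non-shock activity,

        100 * sum_{i in shock} u_i / (sum_{shock} u_i + sum_{non-shock} u_i),

    so 100% means full shock activation with silent non-shock neurons.
    Settled states have strictly positive activities, so the denominator
    cannot vanish there; a degenerate all-zero input raises.
    """
    u = np.asarray(u, dtype=float)
    shock = float(u[layout.shock].sum())
    non_shock = float(u[layout.non_shock].sum())
    total = shock + non_shock
    if total <= 0.0:
        raise ValueError("zero shock + non-shock activity: state is not a settled state")
    return 100.0 * shock / total


def cluster_weight_matrix(weights: np.ndarray, layout: ClusterLayout) -> pd.DataFrame:
    """Mean synaptic weight between each pair of task clusters.

    Entry (P, Q) — row P presynaptic, column Q postsynaptic — is the
    mean of ``w_ij`` over postsynaptic ``i`` in Q and presynaptic ``j``
    in P, including self-connections on the diagonal blocks.  This is
    the cluster-resolved heat-map summary of the full weight matrix.
    """
    weights = np.asarray(weights, dtype=float)
    clusters = layout.named_clusters()
    out = pd.DataFrame(
        index=pd.Index(CLUSTER_ORDER, name="pre_cluster"),
        columns=pd.Index(CLUSTER_ORDER, name="post_cluster"),
        dtype=float,
    )
    for pre_name in CLUSTER_ORDER:
        for post_name in CLUSTER_ORDER:
            block = weights[np.ix_(clusters[post_name], clusters[pre_name])]
            out.loc[pre_name, post_name] = block.mean()
    return out


def aggregate(freezing_table: pd.DataFrame) -> pd.DataFrame:
    """Across-simulation mean and standard error of freezing.

    Expects a tidy table with one row per (simulation, session, probe)
    and a ``freezing_pct`` column, plus any identifying columns such as
    ``group`` and ``drug``.  Returns one row per condition cell with
    ``mean``, ``sem`` and ``n_sims``.  SEM uses the sample standard
    deviation over simulations; a single-simulation cell is degenerate
    and reports SEM 0 (flagged by ``n_sims == 1``).
    """
    if freezing_table.empty:
        raise ValueError("no simulation records to aggregate")
    keys = [
        c for c in ("group", "drug", "session", "probe") if c in freezing_table.columns
    ]
    grouped = freezing_table.groupby(keys, sort=False)["freezing_pct"]
    out = grouped.agg(mean="mean", sem="sem", n_sims="size").reset_index()
    out["sem"] = out["sem"].fillna(0.0)
    return out
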