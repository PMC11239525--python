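"""Cross-modality cluster matching by correlation-structured minimum-cost
maximum-flow (MCMF), with label transfer.

High-resolution chromatin clusters are matched to annotated RNA clusters on
the correlation between mean gene expression and mean gene-activity profiles.
For activating marks the cost of a pair is the correlation distance
1 - r; for the repressive mark H3K27me3 the sign is flipped (1 + r), so
anti-correlated profiles are cheap. The bipartite graph keeps each node's
``knn_k`` cheapest edges plus a null node priced at a percentile of all
costs; an integral min-cost max-flow then decides matches, and clusters
routed to the null node fall back to their minimum-cost counterpart.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COST_SCALE = 10**6  # integral costs for the flow solver


@dataclass
class ClusterProfile:
    """Per-cluster mean profile over a shared, identically ordered feature set."""

    matrix: np.ndarray  # clusters x features
    cluster_ids: list
    features: list[str]
    sizes: np.ndarray
    modality: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.cluster_ids), len(self.features)):
            raise ValueError("profile shape does not match id lists")


@dataclass
class MatchResult:
    pairs: list[tuple]               # (a_cluster, b_cluster, cost)
    unmatched_a: list
    unmatched_b: list
    fallback_pairs: list[tuple] = field(default_factory=list)


def cluster_profiles(
    matrix, labels: pd.Series, features: list[str], modality: str = ""
) -> ClusterProfile:
    """Mean profile per cluster (clusters sorted by id).

    ``matrix`` is cells x features (sparse or dense) aligned with
    ``labels.index``; empty clusters are impossible by construction but a
    label set not covering some cluster id raises.
    """
    import scipy.sparse as sp

    X = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, dtype=float)
    if X.shape[0] != len(labels):
        raise ValueError("one label per matrix row required")
    if X.shape[1] != len(features):
        raise ValueError("feature list does not match matrix columns")
    cluster_ids = sorted(pd.unique(labels))
    rows, sizes = [], []
    for cid in cluster_ids:
        mask = (labels == cid).to_numpy()
        if not mask.any():
            raise ValueError(f"empty cluster {cid}")
        rows.append(X[mask].mean(axis=0))
        sizes.append(int(mask.sum()))
    return ClusterProfile(np.vstack(rows), cluster_ids, list(features), np.asarray(sizes), modality)


def matching_cost(a: ClusterProfile, b: ClusterProfile, sign: int = 1) -> np.ndarray:
    """Pairwise correlation-distance cost matrix: 1 - sign * r(a_i, b_j).

    Zero-variance profiles have undefined correlation; their costs are set to
    the maximum of the defined costs (logged).
    """
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    if a.features != b.features:
        raise ValueError("profiles must share the same ordered feature set")
    A = a.matrix - a.matrix.mean(axis=1, keepdims=True)
    B = b.matrix - b.matrix.mean(axis=1, keepdims=True)
    a_norm = np.linalg.norm(A, axis=1)
    b_norm = np.linalg.norm(B, axis=1)
    degenerate_a, degenerate_b = a_norm == 0, b_norm == 0
    denom = np.outer(np.where(degenerate_a, 1.0, a_norm), np.where(degenerate_b, 1.0, b_norm))
    r = (A @ B.T) / denom
    cost = 1.0 - sign * r
    bad = degenerate_a[:, None] | degenerate_b[None, :]
    if bad.any():
        fill = cost[~bad].max() if (~bad).any() else 2.0
        cost[bad] = fill
        logger.warning(
            "%d zero-variance profiles: their costs set to matrix maximum %.4f",
            int(degenerate_a.sum() + degenerate_b.sum()), fill,
        )
    return cost


def _knn_edge_mask(cost: np.ndarray, knn_k: int) -> np.ndarray:
    """Keep the union of each row's and each column's knn_k cheapest edges."""
    n_a, n_b = cost.shape
    keep = np.zeros_like(cost, dtype=bool)
    k_row = min(knn_k, n_b)
    k_col = min(knn_k, n_a)
    rows = np.argpartition(cost, k_row - 1, axis=1)[:, :k_row]
    for i in range(n_a):
        keep[i, rows[i]] = True
    cols = np.argpartition(cost, k_col - 1, axis=0)[:k_col, :]
    for j in range(n_b):
        keep[cols[:, j], j] = True
    return keep


def mcmf_match(
    cost: np.ndarray,
    knn_k: int = 10,
    null_cost_percentile: float = 99,
    capacity: str = "uniform",
    null_cost: float | None = None,
) -> MatchResult:
    """Solve the sparsified bipartite matching as integral min-cost max-flow.

    Uniform capacity ceil(max(n_a, n_b) / min(n_a, n_b)) on the smaller side
    lets the larger side be fully matched; a null node whose edges cost the
    ``null_cost_percentile`` percentile of all costs absorbs unprofitable
    flow, leaving those clusters unmatched.
    """
    cost = np.asarray(cost, dtype=float)
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix must be finite")
    if capacity != "uniform":
        raise ValueError("only uniform capacity is implemented")
    n_a, n_b = cost.shape
    shift = min(0.0, cost.min())
    work = cost - shift  # min-cost solvers need non-negative costs
    if null_cost is None:
        null_cost = float(np.percentile(work, null_cost_percentile))
    else:
        null_cost = float(null_cost) - shift
    keep = _knn_edge_mask(work, knn_k)

    cap = math.ceil(max(n_a, n_b) / min(n_a, n_b))
    cap_a = cap if n_a <= n_b else 1
    cap_b = cap if n_b < n_a else 1

    g = nx.DiGraph()
    for i in range(n_a):
        g.add_edge("S", ("a", i), capacity=cap_a, weight=0)
        g.add_edge(("a", i), "NULL", capacity=cap_a, weight=int(round(null_cost * _COST_SCALE)))
    for j in range(n_b):
        g.add_edge(("b", j), "T", capacity=cap_b, weight=0)
    g.add_edge("NULL", "T", capacity=n_a * cap_a, weight=0)
    for i, j in zip(*np.nonzero(keep)):
        g.add_edge(
            ("a", int(i)), ("b", int(j)), capacity=1, weight=int(round(work[i, j] * _COST_SCALE))
        )
    try:
        flow = nx.max_flow_min_cost(g, "S", "T")
    except nx.NetworkXUnfeasible as exc:  # pragma: no cover
        isolated = [i for i in range(n_a) if not any(keep[i])]
        raise RuntimeError(f"infeasible flow; isolated a-nodes: {isolated}") from exc

    pairs = []
    for i in range(n_a):
        for node, units in flow[("a", i)].items():
            if units > 0 and node != "NULL":
                j = node[1]
                pairs.append((i, j, float(cost[i, j])))
    pairs.sort()
    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    result = MatchResult(
        pairs=pairs,
        unmatched_a=sorted(set(range(n_a)) - matched_a),
        unmatched_b=sorted(set(range(n_b)) - matched_b),
    )
    logger.info(
        "MCMF: %d pairs, %d/%d unmatched (a/b), null cost %.4f",
        len(pairs), len(result.unmatched_a), len(result.unmatched_b), null_cost + shift,
    )
    return result


def resolve_unmatched(match: MatchResult, cost: np.ndarray) -> MatchResult:
    """Give every unmatched cluster a fallback pair with its minimum-cost
    counterpart (many-to-one allowed; ties broken by lowest cluster id)."""
    cost = np.asarray(cost, dtype=float)
    fallback = list(match.fallback_pairs)
    for i in match.unmatched_a:
        j = int(np.argmin(cost[i]))  # argmin takes the first (lowest) index on ties
        fallback.append((i, j, float(cost[i, j])))
    for j in match.unmatched_b:
        i = int(np.argmin(cost[:, j]))
        fallback.append((i, j, float(cost[i, j])))
    return MatchResult(
        pairs=list(match.pairs),
        unmatched_a=list(match.unmatched_a),
        unmatched_b=list(match.unmatched_b),
        fallback_pairs=sorted(fallback),
    )


def transfer_labels(match: MatchResult, annotations: dict) -> dict:
    """Chromatin (b-side) clusters inherit the state name of their matched
    RNA (a-side) cluster; fallback pairs transfer too."""
    label: dict = {}
    best_cost: dict = {}
    # real pairs win over fallback; among multiple real pairs for one
    # chromatin cluster (uniform capacity > 1) the cheapest one names it
    for tier, pairs in enumerate((match.pairs, match.fallback_pairs)):
        for i, j, cost in pairs:
            if i not in annotations:
                raise KeyError(f"rna cluster {i} has no annotation")
            key = (tier, cost, i)
            if j not in label or (j in best_cost and key < best_cost[j]):
                label[j] = annotations[i]
                best_cost[j] = key
        if tier == 0:
            # fallback may only fill clusters without a real pair
            best_cost = {j: (0, -np.inf, -1) for j in label}
    all_b = {j for _, j, _ in match.pairs} | {j for _, j, _ in match.fallback_pairs}
    missing = set(match.unmatched_b) - all_b
    if missing:
        raise ValueError(f"chromatin clusters with neither pair nor fallback: {sorted(missing)}")
    return label
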