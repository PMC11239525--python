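"""Pseudotime, terminal-fate absorption probabilities, the pruned trajectory
graph, circular fate projection and neighborhood enrichment.

The cell-cell transition matrix is a forward-biased kernel on the kNN graph:
edge weight proportional to exp(beta * (pt(v) - pt(u))), row-normalized, so
mass flows toward later pseudotime. Terminal-fate probabilities are the
absorption probabilities of the chain with the annotated terminal cells made
absorbing (fundamental-matrix solution), so every row is a probability
distribution over terminal states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

from .preprocess import Embedding

logger = logging.getLogger(__name__)

FORWARD_BIAS_BETA = 4.0


@dataclass
class Pseudotime:
    """Rank-normalized pseudotime: sorted values are exactly {1/N, ..., N/N}."""

    values: pd.Series  # cell_id -> (0, 1]

    def __post_init__(self) -> None:
        ranks = np.sort(self.values.to_numpy())
        n = len(ranks)
        if not np.allclose(ranks, np.arange(1, n + 1) / n):
            raise ValueError("pseudotime must be rank/N normalized")


@dataclass
class FateProbabilities:
    matrix: np.ndarray  # cells x terminal states, rows sum to 1
    cell_ids: list[str]
    terminal_states: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if (self.matrix < -1e-12).any():
            raise ValueError("negative fate probabilities")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("fate probability rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.cell_ids, columns=self.terminal_states)


@dataclass
class CircularCoordinates:
    xy: np.ndarray  # cells x 2
    angles: dict[str, float]
    cell_ids: list[str]


def rank_normalize(raw: pd.Series) -> pd.Series:
    """Rank-transform and divide by N; ties broken by cell id for determinism."""
    order = sorted(raw.index, key=lambda c: (raw[c], c))
    n = len(order)
    return pd.Series({c: (i + 1) / n for i, c in enumerate(order)}).loc[raw.index]


def diffusion_pseudotime(embedding: Embedding, root_hint: set[str], n_neighbors: int = 15) -> Pseudotime:
    """Pseudotime as rank/N along the first diffusion component, oriented so
    root cells come first.

    The diffusion map is computed with scanpy on a kNN graph of the embedding;
    a disconnected graph raises with the component sizes.
    """
    import anndata
    import scanpy as sc

    if len(embedding.cell_ids) < 50:
        raise ValueError("need >= 50 cells for a stable diffusion map")
    adata = anndata.AnnData(
        X=np.asarray(embedding.coordinates, dtype=np.float32),
        obs=pd.DataFrame(index=embedding.cell_ids),
    )
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, use_rep="X", random_state=0)
    n_comp, labels = connected_components(adata.obsp["connectivities"], directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(f"kNN graph is disconnected: component sizes {sizes.tolist()}")
    sc.tl.diffmap(adata, n_comps=10)
    dc1 = pd.Series(adata.obsm["X_diffmap"][:, 1], index=embedding.cell_ids)
    pt = rank_normalize(dc1)
    roots = [c for c in embedding.cell_ids if c in root_hint]
    if not roots:
        raise ValueError("no root_hint cells present in embedding")
    if pt.loc[roots].mean() > 0.5:
        pt = rank_normalize(-dc1)
    return Pseudotime(pt)


def transition_matrix(
    embedding: Embedding,
    pseudotime: Pseudotime,
    knn_k: int = 15,
    beta: float = FORWARD_BIAS_BETA,
) -> tuple[sp.csr_matrix, list[str]]:
    """Row-stochastic forward-biased transition matrix on the symmetrized kNN
    graph: weight(u -> v) proportional to exp(beta * (pt(v) - pt(u)))."""
    cells = embedding.cell_ids
    pt = pseudotime.values.loc[cells].to_numpy()
    n = len(cells)
    nn = NearestNeighbors(n_neighbors=min(knn_k + 1, n)).fit(embedding.coordinates)
    _, idx = nn.kneighbors(embedding.coordinates)
    rows, cols = [], []
    for i in range(n):
        for j in idx[i, 1:]:
            rows.append(i)
            cols.append(int(j))
            rows.append(int(j))  # symmetrize so the chain can also step back
            cols.append(i)
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    adj.data = np.ones_like(adj.data)  # dedupe
    adj.setdiag(0)
    adj.eliminate_zeros()
    degrees = np.asarray(adj.sum(axis=1)).ravel()
    if np.any(degrees == 0):
        raise ValueError("isolated cells in the kNN graph")
    adj = adj.tocoo()
    weights = np.exp(beta * (pt[adj.col] - pt[adj.row]))
    T = sp.coo_matrix((weights, (adj.row, adj.col)), shape=(n, n)).tocsr()
    row_sums = np.asarray(T.sum(axis=1)).ravel()
    T = sp.diags(1.0 / row_sums) @ T
    return T.tocsr(), list(cells)


def absorption_probabilities(
    T: sp.spmatrix, cell_ids: list[str], terminal_sets: dict[str, set[str]]
) -> FateProbabilities:
    """Fundamental-matrix absorption probabilities with the terminal cells
    made absorbing. Rows sum to 1; terminal cells get 1 for their own state."""
    names = list(terminal_sets)
    if len(names) == 0:
        raise ValueError("need at least one terminal set")
    for ai, a in enumerate(names):
        for b in names[ai + 1 :]:
            if terminal_sets[a] & terminal_sets[b]:
                raise ValueError(f"terminal sets {a} and {b} overlap")
    index = {c: i for i, c in enumerate(cell_ids)}
    state_of = np.full(len(cell_ids), -1)
    for t, name in enumerate(names):
        members = terminal_sets[name]
        if not members:
            raise ValueError(f"terminal set {name} is empty")
        for c in members:
            state_of[index[c]] = t
    transient = np.nonzero(state_of == -1)[0]
    absorbing = np.nonzero(state_of >= 0)[0]
    T = sp.csr_matrix(T)
    Q = T[transient][:, transient]
    # R grouped by terminal state
    R = np.zeros((len(transient), len(names)))
    R_cells = T[transient][:, absorbing].toarray()
    for k, a in enumerate(absorbing):
        R[:, state_of[a]] += R_cells[:, k]
    A = sp.eye(len(transient), format="csc") - sp.csc_matrix(Q)
    B = np.asarray(spla.spsolve(A, R))
    B = B.reshape(len(transient), len(names))
    row_sums = B.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        bad = [cell_ids[transient[i]] for i in np.nonzero(np.abs(row_sums - 1) > 1e-6)[0][:5]]
        raise ValueError(f"transient cells with no path to any terminal set, e.g. {bad}")
    B = B / row_sums[:, None]  # polish numerical residue to exact distributions
    F = np.zeros((len(cell_ids), len(names)))
    F[transient] = B
    for a in absorbing:
        F[a, state_of[a]] = 1.0
    return FateProbabilities(F, list(cell_ids), names)


@dataclass
class TrajectoryGraph:
    graph: nx.DiGraph  # nodes: cluster ids with pseudotime/region/fate/size

    @property
    def edges(self) -> list[tuple]:
        return list(self.graph.edges)


def build_trajectory_graph(
    cluster_fates: pd.DataFrame,
    cluster_pseudotime: pd.Series,
    cluster_regions: pd.Series,
    k: int = 10,
    wildcard_regions: tuple[str, ...] = ("root", "NE"),
    cluster_sizes: pd.Series | None = None,
) -> TrajectoryGraph:
    """Coarse directed graph over clusters: kNN in fate-vector space, edges
    only forward in pseudotime and never across different regional branches
    (the root / neuroepithelium labels act as wildcards)."""
    clusters = list(cluster_fates.index)
    n = len(clusters)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of clusters ({n})")
    coords = cluster_fates.to_numpy()
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    g = nx.DiGraph()
    for c in clusters:
        g.add_node(
            c,
            pseudotime=float(cluster_pseudotime[c]),
            region=cluster_regions[c],
            fate=cluster_fates.loc[c].to_numpy(),
            size=int(cluster_sizes[c]) if cluster_sizes is not None else 1,
        )
    for i, c in enumerate(clusters):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):
            u, v = c, clusters[int(j)]
            if cluster_pseudotime[u] >= cluster_pseudotime[v]:
                u, v = v, u
            if cluster_pseudotime[u] >= cluster_pseudotime[v]:
                continue  # equal pseudotime: no direction
            ru, rv = cluster_regions[u], cluster_regions[v]
            if ru != rv and ru not in wildcard_regions and rv not in wildcard_regions:
                continue
            g.add_edge(u, v, weight=float(d))
    assert nx.is_directed_acyclic_graph(g)
    return TrajectoryGraph(g)


def circular_projection(fates: FateProbabilities) -> CircularCoordinates:
    """Evenly space the terminal states on the unit circle and project each
    cell: x_i = sum_t f_it cos(alpha_t), y_i = sum_t f_it sin(alpha_t)."""
    n_t = len(fates.terminal_states)
    if n_t < 2:
        raise ValueError("need >= 2 terminal states")
    alphas = 2 * np.pi * np.arange(n_t) / n_t
    xy = np.column_stack([fates.matrix @ np.cos(alphas), fates.matrix @ np.sin(alphas)])
    return CircularCoordinates(
        xy, dict(zip(fates.terminal_states, alphas.tolist())), list(fates.cell_ids)
    )


def knn_enrichment(
    fates: FateProbabilities,
    condition: pd.Series,
    k: int = 100,
    eps: float = 1e-9,
    treated_label: str = "treated",
) -> pd.Series:
    """Per-cell log2 enrichment of treated cells among the k nearest neighbors
    in fate-probability space, relative to the global treated fraction."""
    cond = condition.loc[fates.cell_ids]
    is_treated = (cond == treated_label).to_numpy()
    if is_treated.all() or not is_treated.any():
        raise ValueError("both conditions must be present")
    n = len(fates.cell_ids)
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(fates.matrix)
    _, idx = nn.kneighbors(fates.matrix)
    local = is_treated[idx[:, 1:]].mean(axis=1)
    global_frac = is_treated.mean()
    score = np.log2((local + eps) / (global_frac + eps))
    return pd.Series(score, index=fates.cell_ids, name="knn_enrichment")
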