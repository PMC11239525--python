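"""QC filtering, normalization, chromatin/RNA embeddings, gene-activity
scoring and high-resolution clustering.

QC thresholds follow the source conventions verbatim: RNA cells are kept with
UMI > 2,000 and < 1.5e5, > 1,000 detected genes and mitochondrial fraction
< 0.2 (all strict); chromatin cells with fewer than 200 (H3K27ac, H3K4me3)
or 100 (H3K27me3) fragments are removed, so the boundary count is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .genomic_io import (
    CountMatrix,
    GeneModel,
    GenomicInterval,
    intersect_intervals,
    parse_peak_id,
)

logger = logging.getLogger(__name__)

# fragment-count floor per chromatin modality; cells *below* the floor are removed
CHROMATIN_MIN_FRAGMENTS = {"H3K27ac": 200, "H3K4me3": 200, "H3K27me3": 100, "ATAC": 200}
SCALE_FACTOR = 10_000


@dataclass
class Embedding:
    """Low-dimensional cell embedding (cells x components)."""

    coordinates: np.ndarray
    cell_ids: list[str]
    method: str
    components: list[int]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding contains non-finite values")
        if self.coordinates.shape[0] != len(self.cell_ids):
            raise ValueError("one coordinate row per cell required")


@dataclass
class ClusterLabels:
    labels: pd.Series  # cell_id -> dense integer cluster id from 0
    resolution: float
    modality: str

    def __post_init__(self) -> None:
        ids = np.sort(self.labels.unique())
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("cluster ids must be dense integers from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class GeneActivityMatrix:
    """Log-normalized per-cell gene activity (fragments over gene windows)."""

    values: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    upstream: int


def filter_cells_rna(
    counts: CountMatrix, mito_gene_ids: set[str]
) -> tuple[list[str], pd.DataFrame]:
    """Retain cells with UMI > 2,000, UMI < 1.5e5, detected genes > 1,000 and
    mitochondrial fraction < 0.2. Returns (retained cell ids, QC table)."""
    if counts.modality != "RNA":
        raise ValueError("filter_cells_rna requires an RNA matrix")
    if not mito_gene_ids:
        logger.warning("empty mitochondrial gene set: mito fraction computed as 0")
    umi = counts.cell_totals()
    genes_detected = np.asarray((counts.values > 0).sum(axis=1)).ravel()
    mito_cols = [i for i, f in enumerate(counts.feature_ids) if f in mito_gene_ids]
    if mito_cols:
        mito_counts = np.asarray(counts.values[:, mito_cols].sum(axis=1)).ravel()
        mito_frac = np.divide(mito_counts, umi, out=np.zeros_like(umi, dtype=float), where=umi > 0)
    else:
        mito_frac = np.zeros(counts.n_cells)
    keep = (umi > 2_000) & (umi < 1.5e5) & (genes_detected > 1_000) & (mito_frac < 0.2)
    qc = pd.DataFrame(
        dict(
            cell_id=counts.cell_ids,
            n_umi=umi.astype(int),
            n_genes=genes_detected.astype(int),
            mito_fraction=mito_frac,
            retained=keep,
        )
    )
    logger.info("RNA QC: retained %d / %d cells", int(keep.sum()), counts.n_cells)
    return [c for c, k in zip(counts.cell_ids, keep) if k], qc


def filter_cells_chromatin(counts: CountMatrix) -> list[str]:
    """Remove cells with fewer than 200 (H3K27ac/H3K4me3) or 100 (H3K27me3)
    fragments; a cell exactly at the floor is kept."""
    floor = CHROMATIN_MIN_FRAGMENTS.get(counts.modality)
    if floor is None:
        raise ValueError(f"not a chromatin modality: {counts.modality}")
    totals = counts.cell_totals()
    keep = totals >= floor
    logger.info("%s QC: retained %d / %d cells", counts.modality, int(keep.sum()), counts.n_cells)
    return [c for c, k in zip(counts.cell_ids, keep) if k]


def lognormalize(values: sp.spmatrix, scale: float = SCALE_FACTOR) -> sp.csr_matrix:
    """ln(1 + scale * count / cell_total), sparse-preserving."""
    values = sp.csr_matrix(values, dtype=float)
    totals = np.asarray(values.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("cells with zero total counts must be filtered first")
    scaled = sp.diags(scale / totals) @ values
    scaled.data = np.log1p(scaled.data)
    return scaled.tocsr()


def lognormalize_rna(counts: CountMatrix) -> sp.csr_matrix:
    if counts.modality != "RNA":
        raise ValueError("lognormalize_rna requires an RNA matrix")
    return lognormalize(counts.values)


def tfidf_lsi(
    peak_counts: CountMatrix,
    n_components: int = 30,
    keep_from: int = 2,
    seed: int = 0,
) -> Embedding:
    """TF-IDF transform followed by truncated SVD (latent semantic indexing).

    Term frequency = count / cell total; idf = log(1 + n_cells / (1 + peak
    occurrence count)). Components ``keep_from``..``n_components`` (1-indexed)
    are returned; the first component, which tracks sequencing depth, is
    dropped by default.
    """
    if not (n_components >= keep_from >= 2):
        raise ValueError("require n_components >= keep_from >= 2")
    X = sp.csr_matrix(peak_counts.values, dtype=float)
    if X.nnz == 0:
        raise ValueError("all-zero matrix")
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("cells with zero counts must be filtered first")
    tf = sp.diags(1.0 / totals) @ X
    occurrence = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = np.log(1.0 + X.shape[0] / (1.0 + occurrence))
    tfidf = tf @ sp.diags(idf)
    svd = TruncatedSVD(n_components=n_components, random_state=seed)
    coords = svd.fit_transform(tfidf)
    kept = list(range(keep_from, n_components + 1))
    return Embedding(coords[:, keep_from - 1 : n_components], list(peak_counts.cell_ids), "LSI", kept)


def gene_activity(
    peak_counts: CountMatrix,
    peaks: list[GenomicInterval] | None,
    genes: list[GeneModel],
    upstream: int = 2_000,
) -> GeneActivityMatrix:
    """Per-cell fragment counts summed over each gene body plus ``upstream``
    bp on the promoter side, then log-normalized (scale 10,000).

    Cells with no activity at all stay all-zero (logged), so the matrix keeps
    one row per input cell.
    """
    if peaks is None:
        peaks = [parse_peak_id(p) for p in peak_counts.feature_ids]
    if len(peaks) != len(peak_counts.feature_ids):
        raise ValueError("one interval per peak feature required")
    known_chroms = {p.chrom for p in peaks}
    windows, kept_genes = [], []
    for g in genes:
        if g.body.chrom not in known_chroms:
            logger.warning("gene %s on unknown chrom %s skipped", g.gene_id, g.body.chrom)
            continue
        windows.append(g.activity_window(upstream))
        kept_genes.append(g)
    pairs = intersect_intervals(peaks, windows, slop=0)
    indicator = sp.coo_matrix(
        (np.ones(len(pairs)), tuple(zip(*pairs)) if pairs else ([], [])),
        shape=(len(peaks), len(windows)),
    ).tocsr()
    raw = peak_counts.values @ indicator
    totals = np.asarray(raw.sum(axis=1)).ravel()
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("%d cells with zero gene activity remain all-zero", n_zero)
        totals = np.where(totals == 0, 1.0, totals)
    norm = sp.diags(SCALE_FACTOR / totals) @ sp.csr_matrix(raw, dtype=float)
    norm.data = np.log1p(norm.data)
    return GeneActivityMatrix(
        norm.tocsr(), list(peak_counts.cell_ids), [g.gene_id for g in kept_genes], upstream
    )


def knn_jaccard_graph(coordinates: np.ndarray, knn_k: int = 20):
    """Jaccard-weighted kNN graph (igraph) on Euclidean distances."""
    import igraph

    n = coordinates.shape[0]
    nn = NearestNeighbors(n_neighbors=min(knn_k + 1, n)).fit(coordinates)
    _, idx = nn.kneighbors(coordinates)
    neighbor_sets = [set(row[1:]) for row in idx]
    edges, weights = [], []
    for i in range(n):
        for j in neighbor_sets[i]:
            if i < j or i not in neighbor_sets[j]:
                shared = len(neighbor_sets[i] & neighbor_sets[j])
                union = len(neighbor_sets[i] | neighbor_sets[j])
                edges.append((i, int(j)))
                weights.append(shared / union if union else 0.0)
    graph = igraph.Graph(n=n, edges=edges)
    graph.es["weight"] = [max(w, 1e-6) for w in weights]
    return graph


def cluster_highres(
    embedding: Embedding,
    resolution: float = 1.0,
    knn_k: int = 20,
    seed: int = 0,
) -> ClusterLabels:
    """Louvain-family (Leiden) community detection on a Jaccard-weighted kNN
    graph of the embedding.

    Cells are canonically ordered by id before graph construction, so the
    partition is invariant to the input cell order; given a seed the result
    is deterministic. Cluster ids are dense integers ordered by decreasing
    cluster size.
    """
    import leidenalg

    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    n = len(embedding.cell_ids)
    if n <= knn_k:
        raise ValueError(f"need more cells ({n}) than knn_k ({knn_k})")
    order = np.argsort(np.asarray(embedding.cell_ids, dtype=object))
    graph = knn_jaccard_graph(embedding.coordinates[order], knn_k=knn_k)
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    membership = np.asarray(partition.membership)
    # relabel by decreasing size, ties by original label, for stable ids
    sizes = pd.Series(membership).value_counts()
    relabel = {old: new for new, old in enumerate(sizes.index)}
    labels = np.empty(n, dtype=int)
    labels[order] = [relabel[m] for m in membership]
    series = pd.Series(labels, index=embedding.cell_ids, name="cluster")
    logger.info(
        "clustering at resolution %.2f: %d clusters over %d cells",
        resolution, series.max() + 1, n,
    )
    return ClusterLabels(series, resolution, embedding.method)
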