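"""End-to-end stage drivers over the synthetic dataset.

These functions chain the library modules the way the analysis scripts do:
QC -> embedding -> high-resolution clustering per modality, cross-modality
matching with label transfer, regional differential peaks with
bivalent/switching domain calls, fate-probability trajectory graphs, and
priming-lag recovery. They return plain dicts/frames so tests can assert on
planted truth.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dynamics import first_divergent_bins, pseudotime_lag
from .genomic_io import parse_peak_id
from .matching import (
    ClusterProfile,
    cluster_profiles,
    matching_cost,
    mcmf_match,
    resolve_unmatched,
    transfer_labels,
)
from .preprocess import (
    Embedding,
    cluster_highres,
    filter_cells_chromatin,
    filter_cells_rna,
    gene_activity,
    lognormalize_rna,
    tfidf_lsi,
)
from .states import binarize, call_bivalent, call_switching, detection_rates, differential_peaks
from .synthetic import BRANCHES, MARKS, SyntheticDataset

logger = logging.getLogger(__name__)

MARK_SIGN = {"H3K27ac": 1, "H3K4me3": 1, "H3K27me3": -1}


def cluster_per_group(emb, groups: pd.Series, resolution: float, seed: int, knn_k: int = 20):
    """High-resolution clustering run separately within each timepoint group
    (as sampling timepoints are profiled separately); labels are offset so
    cluster ids are globally unique. Returns (labels, cluster -> group)."""
    from .preprocess import Embedding

    labels = pd.Series(-1, index=emb.cell_ids, dtype=int)
    cluster_group: dict[int, str] = {}
    offset = 0
    for group in sorted(groups.unique()):
        members = [c for c in emb.cell_ids for _ in [0] if groups[c] == group]
        idx = [i for i, c in enumerate(emb.cell_ids) if groups[c] == group]
        sub = Embedding(emb.coordinates[idx], members, emb.method, emb.components)
        k = min(knn_k, len(members) - 1)
        part = cluster_highres(sub, resolution=resolution, knn_k=k, seed=seed)
        labels.loc[members] = part.labels.loc[members] + offset
        for cid in range(part.n_clusters):
            cluster_group[cid + offset] = group
        offset += part.n_clusters
    return labels, cluster_group


def preprocess_chromatin(dataset: SyntheticDataset, mark: str, resolution: float = 0.25, seed: int = 0):
    """QC filter, TF-IDF/LSI embedding and per-timepoint-group
    high-resolution clustering."""
    cm = dataset.counts[mark].subset_cells(filter_cells_chromatin(dataset.counts[mark]))
    emb = tfidf_lsi(cm, n_components=30, keep_from=2, seed=seed)
    meta = dataset.metadata.set_index("cell_id")
    groups = meta.loc[cm.cell_ids, "timepoint_group"]
    labels, cluster_group = cluster_per_group(emb, groups, resolution, seed)
    Y = binarize(cm.values)
    rates = detection_rates(Y, labels.loc[cm.cell_ids], peak_ids=cm.feature_ids)
    return dict(
        counts=cm, embedding=emb, clusters=labels, cluster_group=cluster_group,
        Y=Y, rates=rates,
    )


def preprocess_rna(dataset: SyntheticDataset, n_pcs: int = 20, resolution: float = 0.25, seed: int = 0):
    """QC filter, log-normalization, PCA embedding and per-timepoint-group
    clustering."""
    keep, qc = filter_cells_rna(dataset.counts["RNA"], mito_gene_ids=set())
    cm = dataset.counts["RNA"].subset_cells(keep)
    X = lognormalize_rna(cm)
    coords = PCA(n_components=n_pcs, random_state=seed).fit_transform(np.asarray(X.todense()))
    emb = Embedding(coords, cm.cell_ids, "pca", list(range(1, n_pcs + 1)))
    meta = dataset.metadata.set_index("cell_id")
    groups = meta.loc[cm.cell_ids, "timepoint_group"]
    clusters, cluster_group = cluster_per_group(emb, groups, resolution, seed)
    return dict(
        counts=cm, X=X, embedding=emb, clusters=clusters, cluster_group=cluster_group, qc=qc
    )


def majority_annotation(truth_cells: pd.DataFrame, clusters: pd.Series, column: str) -> pd.Series:
    """Per-cluster majority value of a truth column (ties -> lexicographic)."""
    values = truth_cells.loc[clusters.index, column]
    return values.groupby(clusters).agg(lambda s: s.mode().iloc[0])


def stage_clusters(truth_cells: pd.DataFrame, clusters: pd.Series, timepoint: str = "Mid") -> set:
    """Clusters whose majority timepoint group matches (the NE stage here)."""
    maj = majority_annotation(truth_cells, clusters, "timepoint")
    return set(maj.index[maj == timepoint])


def variable_features(profile: ClusterProfile, n: int = 500) -> list[str]:
    """Top-n features by across-cluster variance of the profile."""
    var = profile.matrix.var(axis=0)
    order = np.argsort(var, kind="mergesort")[::-1][:n]
    return [profile.features[i] for i in sorted(order)]


def subset_profile(profile: ClusterProfile, features: list[str]) -> ClusterProfile:
    index = {f: i for i, f in enumerate(profile.features)}
    cols = [index[f] for f in features]
    return ClusterProfile(
        profile.matrix[:, cols], profile.cluster_ids, list(features), profile.sizes, profile.modality
    )


def match_modalities(
    dataset: SyntheticDataset,
    seed: int = 0,
    n_variable: int = 1000,
    resolution_rna: float = 0.25,
    resolution_chromatin: float = 0.25,
):
    """Full matching arm: per mark, MCMF-match chromatin clusters (gene
    activity) to RNA clusters (expression), transfer the RNA clusters'
    majority state annotation, and score each chromatin cluster's transferred
    label against its own majority true state.

    Clusters are called within timepoint groups, and matching runs within
    each group's block (both modalities sample the same timepoints).
    """
    truth = dataset.truth.cells.set_index("cell_id")
    rna = preprocess_rna(dataset, resolution=resolution_rna, seed=seed)
    rna_labels = rna["clusters"].loc[rna["counts"].cell_ids]
    annot = majority_annotation(truth, rna_labels, "state").to_dict()
    gene_ids = [g.gene_id for g in dataset.genes]
    rna_prof = cluster_profiles(np.asarray(rna["X"].todense()), rna_labels, gene_ids, "RNA")
    rna_groups = rna["cluster_group"]

    out = {}
    for mark in MARKS:
        bits = preprocess_chromatin(dataset, mark, resolution=resolution_chromatin, seed=seed)
        act = gene_activity(bits["counts"], dataset.peaks[mark], dataset.genes)
        labels = bits["clusters"].loc[bits["counts"].cell_ids]
        prof = cluster_profiles(np.asarray(act.values.todense()), labels, act.gene_ids, mark)
        shared = [f for f in variable_features(rna_prof, n_variable) if f in set(prof.features)]
        rna_sub = subset_profile(rna_prof, shared)
        chrom_sub = subset_profile(prof, shared)
        transferred: dict = {}
        matches = []
        for group in sorted(set(bits["cluster_group"].values())):
            a_ids = [c for c in rna_sub.cluster_ids if rna_groups.get(c) == group]
            b_ids = [c for c in chrom_sub.cluster_ids if bits["cluster_group"][c] == group]
            if not a_ids or not b_ids:
                continue
            a_rows = [rna_sub.cluster_ids.index(c) for c in a_ids]
            b_rows = [chrom_sub.cluster_ids.index(c) for c in b_ids]
            cost = matching_cost(
                ClusterProfile(rna_sub.matrix[a_rows], a_ids, shared,
                               rna_sub.sizes[a_rows], "RNA"),
                ClusterProfile(chrom_sub.matrix[b_rows], b_ids, shared,
                               chrom_sub.sizes[b_rows], mark),
                sign=MARK_SIGN[mark],
            )
            match = resolve_unmatched(mcmf_match(cost, knn_k=10, null_cost_percentile=99), cost)
            local = transfer_labels(match, {i: annot[c] for i, c in enumerate(a_ids)})
            transferred.update({b_ids[j]: name for j, name in local.items()})
            matches.append((group, match))
        true_state = majority_annotation(truth, labels, "state")
        accuracy = float(
            np.mean([transferred[c] == true_state[c] for c in true_state.index])
        )
        out[mark] = dict(
            bits=bits, match=matches, transferred=transferred,
            true_state=true_state, accuracy=accuracy,
        )
        logger.info("%s: %d clusters, transfer accuracy %.3f", mark, len(true_state), accuracy)
    return out


def regional_differential(
    dataset: SyntheticDataset, bits: dict, peak_subset: list[str] | None = None
) -> pd.DataFrame:
    """Binomial-GLM differential detection between regional branches for one
    preprocessed mark (cells of the four regional branches only)."""
    truth = dataset.truth.cells.set_index("cell_id")
    cm = bits["counts"]
    region = truth.loc[cm.cell_ids, "region"]
    mask = region.isin(BRANCHES).to_numpy()
    ids = cm.feature_ids
    if peak_subset is not None:
        subset = set(peak_subset)
        cols = [j for j, p in enumerate(ids) if p in subset]
    else:
        cols = list(range(len(ids)))
    Y = pd.DataFrame(
        np.asarray(bits["Y"][mask][:, cols].todense()), columns=[ids[j] for j in cols]
    )
    return differential_peaks(Y, region[mask].to_numpy(), cm.cell_totals()[mask])


def domain_calls(dataset: SyntheticDataset, seed: int = 0):
    """Bivalent and switching domain calling with planted-truth scoring.

    The regional differential test is run on the candidate peaks (the
    cross-mark overlapping pairs), which is the family the callers consult.
    """
    from .genomic_io import intersect_intervals

    bits = {m: preprocess_chromatin(dataset, m, seed=seed) for m in MARKS}
    peaks = {m: [parse_peak_id(p) for p in bits[m]["counts"].feature_ids] for m in MARKS}
    truth = dataset.truth.cells.set_index("cell_id")
    # neuroepithelium-stage clusters: the clusters of the Mid timepoint group
    # (clustering is run within groups, so membership is exact)
    ne = {
        m: {c for c, g in bits[m]["cluster_group"].items() if g == "Mid"}
        for m in MARKS
    }
    candidates: dict[str, set[int]] = {m: set() for m in MARKS}
    for a, b in (("H3K27me3", "H3K4me3"), ("H3K27me3", "H3K27ac")):
        for i, j in intersect_intervals(peaks[a], peaks[b], slop=2_000):
            candidates[a].add(i)
            candidates[b].add(j)
    diff = {
        m: regional_differential(
            dataset, bits[m],
            [bits[m]["counts"].feature_ids[j] for j in sorted(candidates[m])],
        )
        for m in MARKS
    }
    bivalent = call_bivalent(
        peaks["H3K27me3"], peaks["H3K4me3"],
        bits["H3K27me3"]["rates"], bits["H3K4me3"]["rates"],
        diff["H3K27me3"], diff["H3K4me3"],
        ne["H3K27me3"], ne["H3K4me3"],
    )
    switching = call_switching(
        peaks["H3K27me3"], peaks["H3K27ac"],
        bits["H3K27me3"]["rates"], bits["H3K27ac"]["rates"],
        diff["H3K27me3"], diff["H3K27ac"],
        ne["H3K27me3"], ne["H3K27ac"],
    )

    def score(calls, truth_table, a_col, b_col):
        called = set(zip(calls[a_col], calls[b_col])) if len(calls) else set()
        planted = set(zip(truth_table[a_col], truth_table[b_col]))
        tp = len(called & planted)
        return dict(
            n_called=len(called),
            precision=tp / len(called) if called else 0.0,
            recall=tp / len(planted),
        )

    return dict(
        bivalent=bivalent,
        switching=switching,
        bivalent_score=score(bivalent, dataset.truth.bivalent, "me3_peak", "k4_peak"),
        switching_score=score(switching, dataset.truth.switching, "me3_peak", "ac_peak"),
        bits=bits,
        diff=diff,
    )


def priming_recovery(sim: dict) -> pd.DataFrame:
    """Run the inflection-point analysis on a priming simulation and join the
    planted truth: first divergent bin per modality, pseudotime lag."""
    first = {
        "RNA": first_divergent_bins(sim["rna"], sim["bins"], sim["n_fragments"]),
        "chromatin": first_divergent_bins(sim["chromatin"], sim["bins"], sim["n_fragments"]),
    }
    lags = pseudotime_lag(first, rna_key="RNA")
    return lags.join(sim["truth"].set_index("feature"))


def fate_graph_from_truth(
    dataset: SyntheticDataset,
    modality: str = "RNA",
    knn_k: int = 15,
    graph_k: int = 5,
    seed: int = 0,
):
    """Pseudotime + fate probabilities + coarse trajectory graph for one
    modality, using the lineage's terminal neuron states as absorbing sets."""
    from .fate import (
        absorption_probabilities,
        build_trajectory_graph,
        diffusion_pseudotime,
        transition_matrix,
    )

    truth = dataset.truth.cells.set_index("cell_id")
    if modality == "RNA":
        bits = preprocess_rna(dataset, seed=seed)
        emb = bits["embedding"]
    else:
        bits = preprocess_chromatin(dataset, modality, seed=seed)
        emb = bits["embedding"]
    cells = emb.cell_ids
    states = truth.loc[cells, "state"]
    roots = set(states.index[states == dataset.lineage.root])
    pt = diffusion_pseudotime(emb, roots)
    T, order = transition_matrix(emb, pt, knn_k=knn_k)
    terminal_sets = {
        t: set(states.index[states == t]) for t in dataset.lineage.terminal_states
    }
    fates = absorption_probabilities(T, order, terminal_sets)
    labels_obj = bits["clusters"]
    clusters = (labels_obj.labels if hasattr(labels_obj, "labels") else labels_obj).loc[cells]
    fate_df = fates.to_frame()
    cluster_fates = fate_df.groupby(clusters).mean()
    cluster_pt = pt.values.loc[cells].groupby(clusters).mean()
    cluster_region = majority_annotation(truth, clusters, "region")
    graph = build_trajectory_graph(
        cluster_fates, cluster_pt, cluster_region, k=min(graph_k, len(cluster_fates) - 1),
        cluster_sizes=clusters.value_counts(),
    )
    return dict(
        pseudotime=pt, fates=fates, graph=graph, clusters=clusters,
        cluster_region=cluster_region, cluster_pt=cluster_pt,
    )
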