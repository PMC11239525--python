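"""Differential peak detection and chromatin-domain calling.

The differential test follows the detection-rate model: per peak, binarized
counts Y are fit with a binomial GLM (logit link) as Y ~ n_fragments + group
against the null Y ~ n_fragments, compared by likelihood-ratio test with
group-levels-minus-one degrees of freedom and Benjamini-Hochberg correction
across peaks.

Bivalent domains are overlapping H3K4me3/H3K27me3 peak pairs (after +/-2 kb
extension) that are co-detected (>5% of cells) in some neuroepithelium-stage
cluster and resolve with opposite-sign regional enrichment; switching
domains are H3K27me3/H3K27ac pairs where exactly one mark is detected at the
neuroepithelial stage and the silent mark becomes enriched in one branch
while the other is depleted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .genomic_io import (
    GeneModel,
    GenomicInterval,
    interval_gene_distance,
    interval_tss_distance,
    intersect_intervals,
    merge_intervals,
    span_interval,
)
from .preprocess import ClusterLabels, Embedding

logger = logging.getLogger(__name__)

DETECTION_PSEUDOCOUNT = 0.01
SIG_FDR = 0.05
SIG_LFC = 0.25


def binarize(values) -> sp.csr_matrix:
    """Entry 1 iff count > 0."""
    X = sp.csr_matrix(values)
    X = (X > 0).astype(np.int8)
    return X


def detection_lfc(rate_a: np.ndarray, rate_b: np.ndarray, pseudocount: float = DETECTION_PSEUDOCOUNT):
    """log2 fold change of detection rates with a fixed pseudocount."""
    return np.log2((np.asarray(rate_a) + pseudocount) / (np.asarray(rate_b) + pseudocount))


def differential_peaks(
    Y,
    group,
    n_fragments,
    peak_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Binomial-GLM likelihood-ratio test for differential detection.

    Returns one row per (peak, non-reference group level) with the log-odds
    coefficient (``effect``), the detection log2 fold change of that level
    versus all other cells, the per-peak LRT p-value and the BH fdr computed
    across peaks. Degenerate peaks (detected in no or all cells) are reported
    with p = 1 and flagged rather than dropped.
    """
    if sp.issparse(Y):
        Ymat = np.asarray(Y.todense())
    elif isinstance(Y, pd.DataFrame):
        peak_ids = peak_ids or list(Y.columns)
        Ymat = Y.to_numpy()
    else:
        Ymat = np.asarray(Y)
    Ymat = (Ymat > 0).astype(float)
    n_cells, n_peaks = Ymat.shape
    if peak_ids is None:
        peak_ids = [f"peak_{i}" for i in range(n_peaks)]
    group = np.asarray(group)
    frag = np.asarray(n_fragments, dtype=float)
    if np.any(frag <= 0):
        raise ValueError("n_fragments must be positive")
    levels = sorted(pd.unique(group))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    df_lrt = len(levels) - 1

    frag_std = (frag - frag.mean()) / (frag.std() or 1.0)
    X_null = np.column_stack([np.ones(n_cells), frag_std])
    dummies = np.column_stack([(group == lvl).astype(float) for lvl in levels[1:]])
    X_full = np.column_stack([X_null, dummies])
    level_masks = {lvl: group == lvl for lvl in levels}

    rows = []
    pvals = np.ones(n_peaks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(n_peaks):
            y = Ymat[:, j]
            detected = y.sum()
            degenerate = detected == 0 or detected == n_cells
            coefs = dict.fromkeys(levels[1:], 0.0)
            if not degenerate:
                try:
                    full = sm.GLM(y, X_full, family=sm.families.Binomial()).fit(maxiter=50)
                    null = sm.GLM(y, X_null, family=sm.families.Binomial()).fit(maxiter=50)
                    lr = max(0.0, 2.0 * (full.llf - null.llf))
                    pvals[j] = float(chi2.sf(lr, df_lrt))
                    coefs = dict(zip(levels[1:], full.params[2:]))
                except Exception:  # numerical failure counts as no evidence
                    degenerate = True
            for lvl in levels:
                mask = level_masks[lvl]
                rate_in = y[mask].mean()
                rate_out = y[~mask].mean()
                rows.append(
                    dict(
                        peak_id=peak_ids[j],
                        group=lvl,
                        effect=float(coefs.get(lvl, -sum(coefs.values()))),
                        det_lfc=float(detection_lfc(rate_in, rate_out)),
                        rate_in=float(rate_in),
                        rate_out=float(rate_out),
                        p=float(pvals[j]),
                        degenerate=bool(degenerate),
                    )
                )
    fdr = pd.Series(multipletests(pvals, method="fdr_bh")[1], index=peak_ids)
    table = pd.DataFrame(rows)
    table["fdr"] = fdr.loc[table["peak_id"]].to_numpy()
    table["fdr"] = np.maximum(table["fdr"], table["p"])
    return table


def detection_rates(Y, clusters: ClusterLabels | pd.Series, peak_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-cluster detection rate (mean of binary entries): clusters x peaks."""
    labels = clusters.labels if isinstance(clusters, ClusterLabels) else clusters
    if isinstance(Y, pd.DataFrame):
        peak_ids = peak_ids or list(Y.columns)
        X = sp.csr_matrix(Y.to_numpy())
    else:
        X = sp.csr_matrix(Y)
    X = (X > 0).astype(float)
    if peak_ids is None:
        peak_ids = [f"peak_{i}" for i in range(X.shape[1])]
    cluster_ids = sorted(pd.unique(labels))
    rows = []
    lab = np.asarray(labels)
    for cid in cluster_ids:
        mask = lab == cid
        rows.append(np.asarray(X[mask].mean(axis=0)).ravel())
    return pd.DataFrame(rows, index=cluster_ids, columns=peak_ids)


def _significant(diff: pd.DataFrame, fdr: float = SIG_FDR, lfc: float = SIG_LFC) -> pd.DataFrame:
    s = diff[(diff["fdr"] < fdr) & (diff["det_lfc"].abs() > lfc) & ~diff["degenerate"]]
    return s.set_index(["peak_id", "group"])


def _stage_max_rate(rates: pd.DataFrame, stage_clusters) -> pd.Series:
    stage = [c for c in rates.index if c in set(stage_clusters)]
    if not stage:
        raise ValueError("no neuroepithelium-stage clusters in the rate matrix")
    return rates.loc[stage].max(axis=0)


@dataclass
class DomainCallConfig:
    slop: int = 2_000
    min_det: float = 0.05
    fdr: float = SIG_FDR
    lfc: float = SIG_LFC


def call_bivalent(
    me3_peaks: list[GenomicInterval],
    k4_peaks: list[GenomicInterval],
    me3_rates: pd.DataFrame,
    k4_rates: pd.DataFrame,
    me3_diff: pd.DataFrame,
    k4_diff: pd.DataFrame,
    me3_stage_clusters,
    k4_stage_clusters=None,
    slop: int = 2_000,
    min_det: float = 0.05,
) -> pd.DataFrame:
    """Call bivalent H3K4me3/H3K27me3 domains that resolve regionally.

    A pair is called iff (a) both marks are detected in more than ``min_det``
    of cells in at least one neuroepithelium-stage cluster of their own
    modality, and (b) some regional branch shows significant differential
    enrichment of both peaks with opposite signs. Each called pair carries a
    per-branch resolution label: activated (K4me3 up, K27me3 down), repressed
    (K27me3 up, K4me3 down) or stays_bivalent.
    """
    if k4_stage_clusters is None:
        k4_stage_clusters = me3_stage_clusters
    pairs = intersect_intervals(me3_peaks, k4_peaks, slop=slop)
    me3_ne = _stage_max_rate(me3_rates, me3_stage_clusters)
    k4_ne = _stage_max_rate(k4_rates, k4_stage_clusters)
    me3_sig = _significant(me3_diff)
    k4_sig = _significant(k4_diff)
    branches = sorted(set(me3_diff["group"]) | set(k4_diff["group"]))

    rows = []
    for i, j in pairs:
        me3_id = me3_peaks[i].peak_id
        k4_id = k4_peaks[j].peak_id
        if me3_ne.get(me3_id, 0.0) <= min_det or k4_ne.get(k4_id, 0.0) <= min_det:
            continue
        resolution = {}
        opposite = False
        for b in branches:
            m = me3_sig.index.isin([(me3_id, b)]).any()
            k = k4_sig.index.isin([(k4_id, b)]).any()
            label = "stays_bivalent"
            if m and k:
                m_lfc = me3_sig.loc[(me3_id, b), "det_lfc"]
                k_lfc = k4_sig.loc[(k4_id, b), "det_lfc"]
                if k_lfc > 0 and m_lfc < 0:
                    label, opposite = "activated", True
                elif m_lfc > 0 and k_lfc < 0:
                    label, opposite = "repressed", True
            resolution[b] = label
        if not opposite:
            continue
        merged = span_interval([me3_peaks[i].extended(slop), k4_peaks[j].extended(slop)])
        row = dict(me3_peak=me3_id, k4_peak=k4_id, merged_region=merged.peak_id)
        row.update({f"resolution_{b}": lbl for b, lbl in resolution.items()})
        rows.append(row)
    result = pd.DataFrame(rows)
    logger.info("bivalent calls: %d of %d candidate pairs", len(result), len(pairs))
    return result


def call_switching(
    me3_peaks: list[GenomicInterval],
    ac_peaks: list[GenomicInterval],
    me3_rates: pd.DataFrame,
    ac_rates: pd.DataFrame,
    me3_diff: pd.DataFrame,
    ac_diff: pd.DataFrame,
    me3_stage_clusters,
    ac_stage_clusters=None,
    slop: int = 2_000,
    min_det: float = 0.05,
) -> pd.DataFrame:
    """Call H3K27me3 <-> H3K27ac switching domains.

    Overlapping pairs where exactly one mark exceeds ``min_det`` detection in
    a neuroepithelium-stage cluster; the branch of activation is the branch
    where the NE-silent mark is significantly enriched and the NE-detected
    mark significantly depleted (largest silent-mark gain wins ties).
    """
    if ac_stage_clusters is None:
        ac_stage_clusters = me3_stage_clusters
    pairs = intersect_intervals(me3_peaks, ac_peaks, slop=slop)
    me3_ne = _stage_max_rate(me3_rates, me3_stage_clusters)
    ac_ne = _stage_max_rate(ac_rates, ac_stage_clusters)
    me3_sig = _significant(me3_diff)
    ac_sig = _significant(ac_diff)
    branches = sorted(set(me3_diff["group"]) | set(ac_diff["group"]))

    rows = []
    for i, j in pairs:
        me3_id, ac_id = me3_peaks[i].peak_id, ac_peaks[j].peak_id
        me3_on = me3_ne.get(me3_id, 0.0) > min_det
        ac_on = ac_ne.get(ac_id, 0.0) > min_det
        if me3_on == ac_on:
            continue  # both or neither detected at NE: not a switch
        if me3_on:
            gain_sig, gain_id, loss_sig, loss_id = ac_sig, ac_id, me3_sig, me3_id
            direction = "me3_to_ac"
        else:
            gain_sig, gain_id, loss_sig, loss_id = me3_sig, me3_id, ac_sig, ac_id
            direction = "ac_to_me3"
        best_branch, best_gain = None, 0.0
        for b in branches:
            if (gain_id, b) in gain_sig.index and (loss_id, b) in loss_sig.index:
                g = gain_sig.loc[(gain_id, b), "det_lfc"]
                l = loss_sig.loc[(loss_id, b), "det_lfc"]
                if g > 0 and l < 0 and g > best_gain:
                    best_branch, best_gain = b, float(g)
        if best_branch is None:
            continue
        rows.append(
            dict(
                me3_peak=me3_id,
                ac_peak=ac_id,
                branch=best_branch,
                direction=direction,
            )
        )
    result = pd.DataFrame(rows)
    logger.info("switching calls: %d of %d candidate pairs", len(result), len(pairs))
    return result


def classify_locus(
    peaks: list[GenomicInterval],
    genes: list[GeneModel],
    promoter_dist: int = 2_000,
    distal_dist: int = 3_000,
) -> pd.Series:
    """Promoter iff within ``promoter_dist`` of any TSS, distal iff farther
    than ``distal_dist`` from every gene body, other in between."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.body.chrom, []).append(g)
    classes = []
    for pk in peaks:
        cands = by_chrom.get(pk.chrom, [])
        tss_d = min((interval_tss_distance(pk, g) for g in cands), default=None)
        body_d = min((interval_gene_distance(pk, g) for g in cands), default=None)
        if tss_d is not None and tss_d <= promoter_dist:
            classes.append("promoter")
        elif body_d is None or body_d > distal_dist:
            classes.append("distal")
        else:
            classes.append("other")
    return pd.Series(classes, index=[p.peak_id for p in peaks], name="locus_class")


@dataclass
class RegionEmbedding:
    regions: list[str]
    members: dict[str, list[tuple[str, str]]]  # region -> [(modality, peak_id)]
    rate_matrix: pd.DataFrame        # regions x (modality|cluster) detection rates
    processed: pd.DataFrame          # covariate-regressed, z-scaled
    coordinates: np.ndarray          # regions x n_pcs
    cluster_labels: pd.Series        # region -> cluster id
    peak_class: pd.Series            # region -> sorted '+'-joined marks
    locus_class: pd.Series | None


def region_embedding_build(
    rates: dict[str, pd.DataFrame],
    peaks: dict[str, list[GenomicInterval]],
    genes: list[GeneModel] | None = None,
    min_clusters: int = 50,
    min_rate: float = 0.10,
    det_threshold: float = 0.05,
    n_pcs: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> RegionEmbedding:
    """Embed and cluster regulatory regions by their detection pattern.

    Per modality, peaks must be detected (rate > ``det_threshold``) in more
    than ``min_clusters`` high-resolution clusters AND at rate >
    ``min_rate`` in at least one cluster. Survivors are merged across
    modalities by interval overlap into regions; each region is represented
    by its detection rates across all modalities' clusters, z-scaled with
    the number of detected clusters regressed out, then PCA + community
    clustering.
    """
    from .preprocess import cluster_highres

    surviving: list[tuple[str, str, GenomicInterval]] = []
    for modality, rate in rates.items():
        ivs = peaks[modality]
        ids = list(rate.columns)
        if len(ivs) != len(ids):
            raise ValueError(f"{modality}: peak list does not match rate columns")
        n_det = (rate > det_threshold).sum(axis=0)
        keep = (n_det > min_clusters) & (rate.max(axis=0) > min_rate)
        surviving.extend(
            (modality, pid, iv) for pid, iv, k in zip(ids, ivs, keep) if k
        )
        logger.info("%s: %d / %d peaks survive region filters", modality, int(keep.sum()), len(ids))
    if not surviving:
        raise ValueError("no peaks survive the region filters")

    intervals = [s[2] for s in surviving]
    groups = merge_intervals(intervals, slop=0)
    regions, members = [], {}
    region_rows = []
    columns = [
        f"{modality}|{cl}" for modality, rate in rates.items() for cl in rate.index
    ]
    for grp in groups:
        span = span_interval([intervals[i] for i in grp])
        rid = span.peak_id
        regions.append(rid)
        members[rid] = [(surviving[i][0], surviving[i][1]) for i in grp]
        row = []
        for modality, rate in rates.items():
            mine = [pid for m, pid in members[rid] if m == modality]
            if mine:
                row.append(rate[mine].mean(axis=1).to_numpy())
            else:
                row.append(np.zeros(rate.shape[0]))
        region_rows.append(np.concatenate(row))
    rate_matrix = pd.DataFrame(region_rows, index=regions, columns=columns)

    n_detected = (rate_matrix > det_threshold).sum(axis=1).to_numpy(dtype=float)
    X = rate_matrix.to_numpy()
    # regress the detected-cluster-count covariate out of each cluster column,
    # then z-scale columns (features = clusters, observations = regions)
    C = np.column_stack([np.ones(len(regions)), n_detected])
    beta, *_ = np.linalg.lstsq(C, X, rcond=None)
    resid = X - C @ beta
    sd = resid.std(axis=0)
    processed = resid / np.where(sd == 0, 1.0, sd)
    processed_df = pd.DataFrame(processed, index=regions, columns=columns)

    from sklearn.decomposition import PCA

    if len(regions) > 3:
        n_pcs = min(n_pcs, min(processed.shape) - 1)
        coords = PCA(n_components=n_pcs, random_state=seed).fit_transform(processed)
        emb = Embedding(coords, regions, "region_pca", list(range(1, n_pcs + 1)))
        labels = cluster_highres(
            emb, resolution=resolution, knn_k=min(20, len(regions) - 1), seed=seed
        )
        label_series = labels.labels
        coords_out = coords
    else:  # degenerate tiny input: one cluster, no embedding to speak of
        coords_out = np.zeros((len(regions), 1))
        label_series = pd.Series(0, index=regions, name="cluster")

    peak_class = pd.Series(
        {rid: "+".join(sorted({m for m, _ in members[rid]})) for rid in regions}, name="peak_class"
    )
    locus = None
    if genes is not None:
        spans = [span_interval([intervals[i] for i in grp]) for grp in groups]
        locus = classify_locus(spans, genes)
    return RegionEmbedding(
        regions, members, rate_matrix, processed_df, coords_out, label_series, peak_class, locus
    )


def gene_regulatory_census(
    detection: dict[str, pd.DataFrame],
    thresholds: dict[str, float] | None = None,
) -> tuple[pd.Series, dict[str, float]]:
    """Four-way census of genes over the whole timecourse.

    ``detection`` maps modality name -> genes x clusters detection-rate
    frame. A gene is *active* if expression or an activating mark exceeds its
    threshold in at least one cluster, *repressed* if H3K27me3 does. Returns
    (per-gene class, class fractions).
    """
    # the RNA threshold must sit above the leaky baseline detection of
    # unexpressed genes (~0.45 at typical depth) and below expressed genes
    thresholds = {**{"RNA": 0.6, "H3K27ac": 0.05, "H3K4me3": 0.05, "H3K27me3": 0.05},
                  **(thresholds or {})}
    gene_sets = [set(df.index) for df in detection.values()]
    all_genes = sorted(set.union(*gene_sets))
    active = pd.Series(False, index=all_genes)
    repressed = pd.Series(False, index=all_genes)
    for modality, df in detection.items():
        hit = (df > thresholds[modality]).any(axis=1)
        if modality == "H3K27me3":
            repressed |= hit.reindex(all_genes, fill_value=False)
        else:
            active |= hit.reindex(all_genes, fill_value=False)
    classes = pd.Series(
        np.select(
            [active & repressed, active, repressed],
            ["active_and_repressed", "always_active", "inactive_and_repressed"],
            default="inactive_unmarked",
        ),
        index=all_genes,
        name="census_class",
    )
    fractions = (classes.value_counts(normalize=True)).to_dict()
    return classes, fractions


def bulk_peak_lfc(
    intensity: pd.DataFrame,
    design: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Mean log2 fold change of treated versus control peak intensity per
    concentration. ``design`` is indexed by sample with columns 'condition'
    and 'concentration'."""
    controls = design.index[design["condition"] == "control"]
    if len(controls) == 0:
        raise ValueError("no control samples in design")
    ctrl_mean = intensity[controls].mean(axis=1)
    out = {}
    treated = design[design["condition"] != "control"]
    for conc, grp in treated.groupby("concentration"):
        lfcs = [
            np.log2((intensity[s] + pseudocount) / (ctrl_mean + pseudocount))
            for s in grp.index
        ]
        out[conc] = pd.concat(lfcs, axis=1).mean(axis=1)
    return pd.DataFrame(out)
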