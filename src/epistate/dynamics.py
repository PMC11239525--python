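"""Pseudotemporal chromatin and expression dynamics.

Cells are stratified into equal-occupancy pseudotime bins; per-bin detection
rates and mean log-normalized signal feed chromatin-state tracks, spline
smoothing, dynamic-time-warping clustering of multi-modal profiles, and the
epigenetic-priming statistic: the *pseudotime lag*, the number of bins by
which a gene's first significantly divergent chromatin bin precedes its
first divergent RNA bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .states import detection_lfc, differential_peaks

logger = logging.getLogger(__name__)


@dataclass
class PseudotimeBins:
    assignment: pd.Series  # cell_id -> bin index in 1..B
    n_bins: int

    @property
    def counts(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()


def subsample_even(
    cells: pd.DataFrame,
    seed: int = 0,
    floor: int = 100,
    modality_col: str = "modality",
    timepoint_col: str = "timepoint",
) -> dict[str, list[str]]:
    """Per timepoint group, subsample every modality to the smallest modality
    count, but never below ``floor`` (modalities with fewer cells keep all).

    Returns modality -> retained cell ids. Deterministic given the seed; the
    sampling order is canonicalized by cell id.
    """
    rng = np.random.default_rng(seed)
    retained: dict[str, list[str]] = {m: [] for m in cells[modality_col].unique()}
    for tp, grp in cells.groupby(timepoint_col, sort=True):
        counts = grp[modality_col].value_counts()
        target = max(int(counts.min()), floor)
        for modality, sub in grp.groupby(modality_col, sort=True):
            ids = sorted(sub["cell_id"])
            n_keep = min(target, len(ids))
            if n_keep < len(ids):
                keep = rng.choice(len(ids), size=n_keep, replace=False)
                ids = [ids[i] for i in sorted(keep)]
            retained[modality].extend(ids)
    return retained


def bin_pseudotime(pt: pd.Series, n_bins: int) -> PseudotimeBins:
    """Contiguous equal-occupancy bins (sizes differ by at most 1 cell);
    ties are broken by cell id so the split is deterministic."""
    if n_bins > len(pt):
        raise ValueError("more bins than cells")
    order = sorted(pt.index, key=lambda c: (pt[c], c))
    chunks = np.array_split(np.asarray(order, dtype=object), n_bins)
    assignment = pd.Series(
        {c: b + 1 for b, chunk in enumerate(chunks) for c in chunk}, name="bin"
    ).loc[pt.index]
    return PseudotimeBins(assignment, n_bins)


def binned_profile(values, cell_ids: list[str], feature_ids: list[str], bins: PseudotimeBins):
    """(means, detection rates) per feature x bin, from a cells x features
    matrix of log-normalized signal."""
    import scipy.sparse as sp

    X = values.toarray() if sp.issparse(values) else np.asarray(values, dtype=float)
    assign = bins.assignment.loc[cell_ids].to_numpy()
    means = np.zeros((X.shape[1], bins.n_bins))
    rates = np.zeros_like(means)
    for b in range(1, bins.n_bins + 1):
        mask = assign == b
        means[:, b - 1] = X[mask].mean(axis=0)
        rates[:, b - 1] = (X[mask] > 0).mean(axis=0)
    cols = list(range(1, bins.n_bins + 1))
    return (
        pd.DataFrame(means, index=feature_ids, columns=cols),
        pd.DataFrame(rates, index=feature_ids, columns=cols),
    )


DEFAULT_STATE_LABELS = {
    frozenset(): "none",
    frozenset({"H3K27me3"}): "K27me3_only",
    frozenset({"H3K4me3"}): "K4me3_only",
    frozenset({"H3K27ac"}): "K27ac_only",
    frozenset({"H3K27me3", "H3K4me3"}): "bivalent",
    frozenset({"H3K27ac", "H3K4me3"}): "co_active",
    # H3K27me3 with H3K27ac on the same residue is biologically implausible;
    # flagged rather than given an "active" label
    frozenset({"H3K27me3", "H3K27ac"}): "conflict",
    frozenset({"H3K27me3", "H3K27ac", "H3K4me3"}): "conflict",
}


def chromatin_state_track(
    detection: dict[str, pd.DataFrame],
    min_det: float = 0.05,
    labels: dict[frozenset, str] = DEFAULT_STATE_LABELS,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-region, per-bin chromatin-state labels.

    Eligible regions have all marks detected above ``min_det`` in some bin.
    Each mark's on/off threshold is the median detection over eligible
    regions x bins for that mark; per bin a region's label is determined by
    the set of marks above threshold. Returns (labels frame, thresholds).
    """
    marks = list(detection)
    regions = detection[marks[0]].index
    for m in marks[1:]:
        if not detection[m].index.equals(regions):
            raise ValueError("all marks must share the same region index")
    eligible = pd.Series(True, index=regions)
    for m in marks:
        eligible &= (detection[m] > min_det).any(axis=1)
    if not eligible.any():
        raise ValueError("no eligible regions (all marks above threshold in some bin)")
    thresholds = {
        m: float(np.median(detection[m].loc[eligible].to_numpy())) for m in marks
    }
    elig_idx = regions[eligible]
    n_bins = detection[marks[0]].shape[1]
    out = pd.DataFrame("none", index=elig_idx, columns=detection[marks[0]].columns)
    on = {m: detection[m].loc[elig_idx] > thresholds[m] for m in marks}
    for col in out.columns:
        combos = [
            frozenset(m for m in marks if on[m].loc[r, col]) for r in elig_idx
        ]
        out[col] = [labels.get(c, "other") for c in combos]
    return out, thresholds


def smooth_profile(binned: pd.DataFrame) -> pd.DataFrame:
    """Cubic smoothing-spline fit per feature over the bin axis, with the
    smoothing parameter chosen by generalized cross-validation. Constant
    profiles are returned unchanged."""
    if binned.shape[1] < 8:
        raise ValueError("need >= 8 bins for spline smoothing")
    x = np.arange(binned.shape[1], dtype=float)
    out = np.empty_like(binned.to_numpy(), dtype=float)
    for i, (_, row) in enumerate(binned.iterrows()):
        y = row.to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            out[i] = y
            continue
        try:
            spl = make_smoothing_spline(x, y)  # lam=None -> GCV
            out[i] = spl(x)
        except Exception:  # degenerate numerics: leave unsmoothed
            out[i] = y
    return pd.DataFrame(out, index=binned.index, columns=binned.columns)


def stack_modalities(profiles: dict[str, pd.DataFrame], zscale: bool = True) -> dict[str, np.ndarray]:
    """Per feature, stack per-modality bin profiles into a (modalities x bins)
    array; each modality profile is z-scaled per feature so no modality
    dominates the DTW local cost."""
    feats = None
    for df in profiles.values():
        feats = df.index if feats is None else feats.intersection(df.index)
    stacked = {}
    for f in feats:
        rows = []
        for m, df in profiles.items():
            y = df.loc[f].to_numpy(dtype=float)
            if zscale:
                sd = y.std()
                y = (y - y.mean()) / sd if sd > 0 else y - y.mean()
            rows.append(y)
        stacked[f] = np.vstack(rows)
    return stacked


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Dynamic-time-warping distance between two (modalities x bins) profiles.

    Symmetric step pattern (diagonal, horizontal, vertical), local cost the
    Euclidean distance between stacked per-bin vectors, no warping window.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("profiles must share the modality set")
    n, m = a.shape[1], b.shape[1]
    local = np.sqrt(((a[:, :, None] - b[:, None, :]) ** 2).sum(axis=0))
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = local[i - 1, j - 1] + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    return float(D[n, m])


def dtw_distance_matrix(stacked: dict[str, np.ndarray]) -> pd.DataFrame:
    feats = list(stacked)
    n = len(feats)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(stacked[feats[i]], stacked[feats[j]])
    return pd.DataFrame(D, index=feats, columns=feats)


def cluster_profiles_dtw(
    distance: pd.DataFrame, k: int, seed: int = 0, max_iter: int = 100
) -> tuple[pd.Series, list[str]]:
    """k-medoids (PAM-style) partition of a precomputed distance matrix.

    The distance-native analogue of k-means: medoids are actual features, so
    DTW distances need not live in a vector space. Deterministic given the
    seed; returns (assignment, medoid ids).
    """
    D = distance.to_numpy()
    n = D.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of features")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("need a symmetric zero-diagonal distance matrix")
    rng = np.random.default_rng(seed)
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    prev_cost = np.inf
    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        cost = D[np.arange(n), medoids[assign]].sum()
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.nonzero(assign == c)[0]
            if len(members) == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]  # argmin: lowest index on ties
        if cost >= prev_cost and np.array_equal(new_medoids, medoids):
            break
        prev_cost = cost
        medoids = new_medoids
    assign = np.argmin(D[:, medoids], axis=1)
    feats = list(distance.index)
    return (
        pd.Series(assign, index=feats, name="dtw_cluster"),
        [feats[m] for m in medoids],
    )


def first_divergent_bins(
    Y: pd.DataFrame,
    bins: pd.Series,
    n_fragments: pd.Series,
    baseline_bin: int = 1,
    direction: int = 1,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 0.25,
) -> pd.Series:
    """First pseudotime bin whose detection rate diverges from the baseline.

    Every bin b > baseline is tested against the baseline bin with the
    binomial-GLM differential-detection test; BH correction spans all
    (bin, feature) tests of the run. The result per feature is the smallest
    bin with fdr < ``fdr_threshold`` and log2 detection fold change >
    ``lfc_threshold`` (direction = -1 for repressive marks flips the
    qualifying sign), or NaN when no bin qualifies.
    """
    from statsmodels.stats.multitest import multipletests

    cells = Y.index
    assign = bins.loc[cells]
    base_mask = (assign == baseline_bin).to_numpy()
    if not base_mask.any():
        raise ValueError("empty baseline bin")
    all_bins = sorted(b for b in assign.unique() if b != baseline_bin)
    records = []
    for b in all_bins:
        mask = base_mask | (assign == b).to_numpy()
        sub = Y.loc[mask]
        grp = np.where((assign[mask] == b).to_numpy(), "bin", "base")
        table = differential_peaks(
            sub, grp, n_fragments.loc[cells][mask].to_numpy(), peak_ids=list(Y.columns)
        )
        table = table[table["group"] == "bin"].copy()
        table["bin"] = b
        records.append(table)
    tests = pd.concat(records, ignore_index=True)
    tests["fdr"] = multipletests(tests["p"], method="fdr_bh")[1]

    qualifying = tests[
        (tests["fdr"] < fdr_threshold)
        & (direction * tests["det_lfc"] > lfc_threshold)
        & ~tests["degenerate"]
    ]
    first = qualifying.groupby("peak_id")["bin"].min()
    return first.reindex(Y.columns).astype(float)


def pseudotime_lag(first_bins: dict[str, pd.Series], rna_key: str = "RNA") -> pd.DataFrame:
    """Lag = first divergent RNA bin minus first divergent chromatin bin;
    positive values mean the chromatin change precedes expression (priming).
    Undefined when either bin is missing."""
    if rna_key not in first_bins:
        raise ValueError(f"no {rna_key!r} entry in first_bins")
    rna = first_bins[rna_key]
    out = pd.DataFrame({f"bin_{rna_key}": rna})
    for modality, series in first_bins.items():
        if modality == rna_key:
            continue
        out[f"bin_{modality}"] = series.reindex(rna.index)
        out[f"lag_{modality}"] = rna - out[f"bin_{modality}"]
    return out


def annotate_network_edges(
    edges: pd.DataFrame,
    detection: dict[str, pd.DataFrame],
    min_det: float = 0.05,
) -> pd.DataFrame:
    """Per-edge, per-bin epigenomic state of a provided regulatory network.

    ``edges`` needs columns (factor, target, region); per bin the state is
    the '+'-joined set of marks whose detection at the edge's region exceeds
    ``min_det`` ('none' if empty). Unresolvable regions are flagged and
    skipped.
    """
    marks = list(detection)
    bins = detection[marks[0]].columns
    rows = []
    for edge in edges.itertuples():
        known = [m for m in marks if edge.region in detection[m].index]
        if not known:
            logger.warning("edge %s->%s: region %s unresolvable", edge.factor, edge.target, edge.region)
            rows.append(
                dict(factor=edge.factor, target=edge.target, region=edge.region,
                     bin=np.nan, state="unresolved")
            )
            continue
        for b in bins:
            on = sorted(m for m in known if detection[m].loc[edge.region, b] > min_det)
            rows.append(
                dict(factor=edge.factor, target=edge.target, region=edge.region,
                     bin=b, state="+".join(on) if on else "none")
            )
    return pd.DataFrame(rows)
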