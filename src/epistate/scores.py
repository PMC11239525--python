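"""Perturbation-arm statistics and epigenetic scores.

Covers background-matched module scores and the bivalency score
(z(activation) - z(repression) over clusters), R-squared partitioning of
cluster means into regional and pseudotemporal variance, the stratified
Cochran-Mantel-Haenszel composition test, logistic-regression differential
expression with the treatment as the response, Fisher-exact motif
enrichment, and the proximity rule selecting perturbation-responsive
regions for motif testing.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.stats import chi2, fisher_exact
from statsmodels.stats.contingency_tables import StratifiedTable, Table2x2
from statsmodels.stats.multitest import multipletests

from .genomic_io import GeneModel, GenomicInterval, interval_gene_distance

logger = logging.getLogger(__name__)


def module_score(
    activity,
    feature_ids: list[str],
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell deviation of a gene set from a background matched on average
    activity.

    Features are binned by their dataset-wide mean activity; each gene in the
    set draws ``n_ctrl`` control features from its own bin, and the score is
    mean(set) - mean(controls) per cell.
    """
    if len(gene_set) < 2:
        raise ValueError("gene set must contain at least 2 features")
    X = activity.toarray() if sp.issparse(activity) else np.asarray(activity, dtype=float)
    index = {f: i for i, f in enumerate(feature_ids)}
    missing = [g for g in gene_set if g not in index]
    if missing:
        raise KeyError(f"gene set members absent from features: {missing[:5]}")
    rng = np.random.default_rng(seed)
    avg = X.mean(axis=0)
    order = np.argsort(avg, kind="mergesort")
    bin_of = np.empty(len(feature_ids), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b
    in_set = np.zeros(len(feature_ids), dtype=bool)
    in_set[[index[g] for g in gene_set]] = True
    ctrl_cols: list[np.ndarray] = []
    for g in gene_set:
        pool = np.nonzero((bin_of == bin_of[index[g]]) & ~in_set)[0]
        if len(pool) == 0:  # set fills its bin: fall back to the whole bin
            pool = np.nonzero(bin_of == bin_of[index[g]])[0]
        ctrl_cols.append(rng.choice(pool, size=min(n_ctrl, len(pool)), replace=False))
    ctrl = np.unique(np.concatenate(ctrl_cols))
    set_cols = np.array([index[g] for g in gene_set])
    return X[:, set_cols].mean(axis=1) - X[:, ctrl].mean(axis=1)


def bivalency_score(k4_scores: pd.Series, me3_scores: pd.Series) -> pd.DataFrame:
    """zscale(activation score) - zscale(repression score) over clusters:
    near 0 means bivalent, positive activation-dominant, negative
    repression-dominant."""
    clusters = k4_scores.index
    if not clusters.equals(me3_scores.index):
        raise ValueError("scores must share the cluster universe")
    if len(clusters) < 3:
        raise ValueError("need >= 3 clusters for a stable z-scale")

    def z(s: pd.Series) -> pd.Series:
        sd = s.std(ddof=0)
        return (s - s.mean()) / (sd if sd > 0 else 1.0)

    za, zr = z(k4_scores), z(me3_scores)
    return pd.DataFrame(
        dict(activation_z=za, repression_z=zr, bivalency=za - zr), index=clusters
    )


def regional_variance(
    cluster_means: pd.DataFrame,
    region: pd.Series,
    pseudotime: pd.Series,
) -> pd.DataFrame:
    """Per-feature R-squared of cluster means under three OLS models:
    ~region, ~pseudotime, ~pseudotime + region.

    Constant features get R-squared 0 under all models.
    """
    clusters = cluster_means.columns
    regions = pd.get_dummies(region.loc[clusters], drop_first=True).to_numpy(dtype=float)
    if regions.shape[1] == 0:
        raise ValueError("need >= 2 regions")
    pt = pseudotime.loc[clusters].to_numpy(dtype=float)[:, None]
    ones = np.ones((len(clusters), 1))
    designs = {
        "r2_region": np.hstack([ones, regions]),
        "r2_pseudotime": np.hstack([ones, pt]),
        "r2_both": np.hstack([ones, pt, regions]),
    }
    Y = cluster_means.to_numpy(dtype=float).T  # clusters x features
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    out = {}
    for name, X in designs.items():
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        rss = ((Y - X @ beta) ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
        out[name] = np.clip(r2, 0.0, 1.0)
    return pd.DataFrame(out, index=cluster_means.index)


def cmh_composition(
    cluster: pd.Series,
    condition: pd.Series,
    strata: pd.Series,
    treated_label: str = "treated",
    sig_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Per-cluster Cochran-Mantel-Haenszel test of composition shifts.

    For each cluster a 2x2xK table (in-cluster vs out x treated vs control x
    stratum) is built; strata with an empty margin are dropped (logged).
    Reports the Mantel-Haenszel common odds ratio, the two-sided
    continuity-corrected chi-square p-value, BH fdr, and a significance flag
    at fdr < ``sig_threshold``.
    """
    is_treated = (condition == treated_label).to_numpy()
    if is_treated.all() or not is_treated.any():
        raise ValueError("both conditions required")
    rows = []
    for cl in sorted(cluster.unique()):
        in_cluster = (cluster == cl).to_numpy()
        tables = []
        for s in sorted(strata.unique()):
            m = (strata == s).to_numpy()
            a = int((in_cluster & is_treated & m).sum())
            b = int((in_cluster & ~is_treated & m).sum())
            c = int((~in_cluster & is_treated & m).sum())
            d = int((~in_cluster & ~is_treated & m).sum())
            table = np.array([[a, b], [c, d]])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                logger.info("cluster %s: stratum %s dropped (empty margin)", cl, s)
                continue
            tables.append(table)
        if not tables:
            rows.append(dict(cluster=cl, odds_ratio=np.nan, p=1.0))
            continue
        st = StratifiedTable(np.stack(tables, axis=-1).astype(float))
        # continuity correction only when some cell is zero; a perfectly
        # balanced table then gives chi-square 0 and p = 1
        correct = any(t.min() == 0 for t in tables)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            test = st.test_null_odds(correction=correct)
        rows.append(dict(cluster=cl, odds_ratio=float(st.oddsratio_pooled), p=float(test.pvalue)))
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
    out["significant"] = out["fdr"] < sig_threshold
    return out


def mantel_haenszel_or(tables: list[np.ndarray]) -> float:
    """Common odds ratio by the standard formula sum(a_k d_k / n_k) /
    sum(b_k c_k / n_k); independent of the statsmodels implementation."""
    num = sum(t[0, 0] * t[1, 1] / t.sum() for t in tables)
    den = sum(t[0, 1] * t[1, 0] / t.sum() for t in tables)
    return num / den


def de_logistic(
    Y,
    condition: pd.Series,
    covariates: pd.DataFrame,
    gene_ids: list[str] | None = None,
    treated_label: str = "treated",
    fdr_threshold: float = 0.01,
    lfc_threshold: float = 0.1,
) -> pd.DataFrame:
    """Logistic-regression differential expression for the perturbation arm.

    The model orientation has the treatment as the response:
    treatment ~ gene_detection + covariates, tested against the
    covariate-only null by a 1-df likelihood-ratio test. Detection log2 fold
    changes use pseudocount 0.01; significance is fdr < 0.01 AND
    |log2FC| > 0.1. Genes that perfectly separate the conditions fall back
    to a Fisher exact p-value and are flagged.
    """
    if sp.issparse(Y):
        Ymat = np.asarray(Y.todense())
    elif isinstance(Y, pd.DataFrame):
        gene_ids = gene_ids or list(Y.columns)
        Ymat = Y.to_numpy()
    else:
        Ymat = np.asarray(Y)
    Ymat = (Ymat > 0).astype(float)
    if gene_ids is None:
        gene_ids = [f"gene_{i}" for i in range(Ymat.shape[1])]
    t = (condition == treated_label).to_numpy().astype(float)
    if t.all() or not t.any():
        raise ValueError("both conditions required")

    cov_parts = [np.ones(len(t))]
    for col in covariates.columns:
        vals = covariates[col]
        if pd.api.types.is_numeric_dtype(vals):
            v = vals.to_numpy(dtype=float)
            if v.std() > 0:  # constant covariates are the intercept
                cov_parts.append((v - v.mean()) / v.std())
        else:
            dummies = pd.get_dummies(vals, drop_first=True)
            for c in dummies.columns:
                d = dummies[c].to_numpy(dtype=float)
                if d.std() > 0:
                    cov_parts.append(d)
    X_null = np.column_stack(cov_parts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null_fit = sm.Logit(t, X_null).fit(disp=0, maxiter=100)
    llf_null = null_fit.llf

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, gene in enumerate(gene_ids):
            y = Ymat[:, j]
            rate_t = y[t == 1].mean()
            rate_c = y[t == 0].mean()
            lfc = float(np.log2((rate_t + 0.01) / (rate_c + 0.01)))
            flagged = False
            if y.std() == 0:
                p, coef = 1.0, 0.0
            else:
                X_full = np.column_stack([X_null, y])
                try:
                    fit = sm.Logit(t, X_full).fit(disp=0, maxiter=100)
                    if not np.isfinite(fit.llf) or np.abs(fit.params[-1]) > 25:
                        raise np.linalg.LinAlgError("separation")
                    lr = max(0.0, 2.0 * (fit.llf - llf_null))
                    p = float(chi2.sf(lr, 1))
                    coef = float(fit.params[-1])
                except Exception:
                    tab = np.array(
                        [
                            [int((y[t == 1] > 0).sum()), int((y[t == 1] == 0).sum())],
                            [int((y[t == 0] > 0).sum()), int((y[t == 0] == 0).sum())],
                        ]
                    )
                    p = float(fisher_exact(tab)[1])
                    coef = np.sign(lfc) * 25.0
                    flagged = True
            rows.append(
                dict(gene_id=gene, coef=coef, det_lfc=lfc, rate_treated=float(rate_t),
                     rate_control=float(rate_c), p=p, separation_fallback=flagged)
            )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = (out["fdr"] < fdr_threshold) & (out["det_lfc"].abs() > lfc_threshold)
    return out


def motif_enrichment(
    foreground: set[str],
    background: set[str],
    occurrences: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Fisher exact test per motif on foreground vs background
    occurrence counts; motifs absent everywhere are skipped. The odds ratio
    for extreme tables uses a 0.5 pseudo-count (reported as a bounded
    estimate)."""
    fg = sorted(foreground & set(occurrences.index))
    bg = sorted((background - foreground) & set(occurrences.index))
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty within the table")
    rows = []
    for motif in occurrences.columns:
        col = occurrences[motif] > 0
        a = int(col.loc[fg].sum()); b = len(fg) - a
        c = int(col.loc[bg].sum()); d = len(bg) - c
        if a + c == 0:
            continue
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        or_haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append(
            dict(motif=motif, fg_hit=a, fg_miss=b, bg_hit=c, bg_miss=d,
                 odds_ratio=float(or_haldane), p=float(p))
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["fdr"] < fdr_threshold
    return out


def select_perturbation_regions(
    de_table: pd.DataFrame,
    peak_lfc: pd.Series,
    peaks: list[GenomicInterval],
    genes: list[GeneModel],
    window: int = 10_000,
    de_fdr: float = 1e-4,
    de_lfc: float = 1.0,
    peak_lfc_max: float = -1.0,
) -> list[str]:
    """Peaks within ``window`` bp of genes upregulated in the perturbation
    (fdr < 1e-4, log2FC > 1) that are themselves depleted (log2FC < -1)."""
    passing = set(
        de_table.loc[(de_table["fdr"] < de_fdr) & (de_table["det_lfc"] > de_lfc), "gene_id"]
    )
    gene_models = [g for g in genes if g.gene_id in passing]
    selected = []
    for pk in peaks:
        lfc = peak_lfc.get(pk.peak_id)
        if lfc is None or not lfc < peak_lfc_max:
            continue
        if any(interval_gene_distance(pk, g) < window for g in gene_models):
            selected.append(pk.peak_id)
    return selected
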