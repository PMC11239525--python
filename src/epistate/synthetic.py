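"""Multi-modal synthetic single-cell datasets with planted ground truth.

The generator emulates the statistical structure of a neural-organoid
timecourse profiled with scRNA-seq and single-cell CUT&Tag for three histone
marks (H3K27ac, H3K4me3, H3K27me3):

* a branching lineage (pluripotent stem cells -> neuroepithelium -> four
  regional branches, each progenitor -> neuron), with per-cell pseudotime;
* sparse, binary-ish chromatin detection with per-cell depth variation
  (fragment counts are Binomial with a depth-scaled success probability, so
  the per-state detection rate of a peak equals its planted probability at
  median depth);
* negative-binomial RNA counts;
* planted branch-specific peaks, bivalent (H3K4me3+H3K27me3) regions that
  resolve in one branch, H3K27me3->H3K27ac switching regions, decoy regions
  that must NOT be called, and telencephalic neuronal genes whose chromatin
  activation precedes RNA expression by a known number of pseudotime bins.

Each modality gets its own cells (as in the real assays); state-level
parameters are shared, so chromatin clusters are generated from the same
states that define the RNA annotation — the basis for the cluster-matching
recovery checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genomic_io import (
    CountMatrix,
    GeneModel,
    GenomicInterval,
    write_gene_models,
    write_mtx_triplet,
    write_peak_bed,
)

logger = logging.getLogger(__name__)

MARKS = ("H3K27ac", "H3K4me3", "H3K27me3")
BRANCHES = ("telencephalon", "diencephalon", "mes_rhombencephalon", "retina")


@dataclass(frozen=True)
class StateSpec:
    name: str
    parent: str | None
    n_cells: int
    pt_range: tuple[float, float]
    region: str
    stage: str
    timepoint: str
    terminal: bool = False


@dataclass
class LineageSpec:
    """Branching lineage: a tree of states with pseudotime ranges in [0, 1]."""

    states: dict[str, StateSpec]

    def __post_init__(self) -> None:
        roots = [s for s in self.states.values() if s.parent is None]
        if len(roots) != 1:
            raise ValueError("lineage must have exactly one root state")
        for s in self.states.values():
            if s.parent is not None and s.parent not in self.states:
                raise ValueError(f"state {s.name} has unknown parent {s.parent}")
        # connectivity + acyclicity + pseudotime monotonicity via root walk
        seen: set[str] = set()
        stack = [roots[0].name]
        while stack:
            name = stack.pop()
            if name in seen:
                raise ValueError("lineage tree contains a cycle")
            seen.add(name)
            for child in (s for s in self.states.values() if s.parent == name):
                if child.pt_range[0] < self.states[name].pt_range[0]:
                    raise ValueError(
                        f"pseudotime range of {child.name} does not increase from {name}"
                    )
                stack.append(child.name)
        unreachable = set(self.states) - seen
        if unreachable:
            raise ValueError(f"unreachable states in tree: {sorted(unreachable)}")
        if len(self.terminal_states) < 2:
            raise ValueError("need >= 2 terminal states")

    @property
    def state_names(self) -> list[str]:
        return list(self.states)

    @property
    def terminal_states(self) -> list[str]:
        return [s.name for s in self.states.values() if s.terminal]

    @property
    def root(self) -> str:
        return next(s.name for s in self.states.values() if s.parent is None)


def default_lineage(cells_scale: float = 1.0) -> LineageSpec:
    """PSC -> neuroepithelium -> 4 regional branches (NPC -> neuron)."""
    states = {
        "PSC": StateSpec("PSC", None, round(400 * cells_scale), (0.0, 0.18), "root", "pluripotent", "EB"),
        "neuroepithelium": StateSpec(
            "neuroepithelium", "PSC", round(450 * cells_scale), (0.18, 0.40), "NE", "neuroepithelium", "Mid"
        ),
    }
    for branch in BRANCHES:
        npc = f"{branch}_npc"
        states[npc] = StateSpec(
            npc, "neuroepithelium", round(250 * cells_scale), (0.40, 0.70), branch, "npc", "Late"
        )
        neuron = f"{branch}_neuron"
        states[neuron] = StateSpec(
            neuron, npc, round(180 * cells_scale), (0.70, 1.00), branch, "neuron", "Neu", terminal=True
        )
    return LineageSpec(states)


@dataclass
class EmissionSpec:
    """Noise model parameters.

    depth_sigma is the log-normal sd of the per-cell depth factor (median 1).
    Chromatin fragment counts per (cell, peak) are Binomial(trials, q) with
    q = 1 - (1 - p)^(s / trials) for depth factor s, so P(count > 0) equals
    1 - (1 - p)^s: the planted detection probability p at median depth.
    RNA counts are negative binomial with gene/state means and a common
    dispersion (gamma shape) parameter.
    """

    depth_sigma: float = 0.35
    rna_dispersion: float = 2.0
    trials: int = 4
    expr_high: float = 8.0
    expr_mid: float = 4.0
    expr_low: float = 0.6

    def __post_init__(self) -> None:
        if self.rna_dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.depth_sigma < 0:
            raise ValueError("depth_sigma must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth: the acceptance oracle for the whole pipeline."""

    cells: pd.DataFrame          # cell_id, modality, state, region, stage, timepoint, pseudotime
    bivalent: pd.DataFrame       # gene_id, k4_peak, me3_peak, branch, resolution
    switching: pd.DataFrame      # gene_id, me3_peak, ac_peak, branch
    primed: pd.DataFrame         # gene_id, ac_peak, lag_bins, chrom_bin, rna_bin
    gene_classes: pd.DataFrame   # gene_id, category, census_class
    marker_peaks: pd.DataFrame   # peak_id, modality, branch


@dataclass
class SyntheticDataset:
    counts: dict[str, CountMatrix]
    metadata: pd.DataFrame
    peaks: dict[str, list[GenomicInterval]]
    genes: list[GeneModel]
    truth: SyntheticTruth
    lineage: LineageSpec
    emission: EmissionSpec


# ---------------------------------------------------------------------------
# gene / peak design
# ---------------------------------------------------------------------------

# number of genes per planted category at the default 2,000-gene scale
_CATEGORY_SIZES = {
    "housekeeping": 550,
    "progenitor": 100,
    "silent": 75,
    "pluripotency": 100,
    "neuroepithelial": 100,
    "repressed": 300,
    "marker": 400,            # 100 per branch
    "bivalent": 50,
    "decoy_bivalent_lowNE": 50,
    "decoy_bivalent_flat": 50,
    "switching": 50,
    "decoy_switch_both": 50,
    "decoy_switch_flat": 25,
    "primed": 100,
}

_GENE_SPACING = 20_000
_GENE_BODY = 2_000
_PEAK_HALF = 250
_DISTAL_OFFSET = 8_000
PRIMING_BINS = 20  # reference binning for planted priming lags


def _gene_position(idx: int) -> tuple[str, int]:
    chrom = f"chr{idx // 1000 + 1}"
    return chrom, 100_000 + (idx % 1000) * _GENE_SPACING


@dataclass
class _PeakDesign:
    interval: GenomicInterval
    p: np.ndarray  # per-state detection probability
    gene_id: str | None = None
    role: str = "fill"


def _design_genes_and_peaks(
    lineage: LineageSpec, emission: EmissionSpec, n_fill: dict[str, int], rng: np.random.Generator
):
    """Lay out genes on the genome and assign per-state expression means and
    per-mark peak detection probabilities according to the planted categories."""
    states = lineage.state_names
    ns = len(states)
    s_idx = {s: i for i, s in enumerate(states)}

    def vec(default: float, **overrides: float) -> np.ndarray:
        v = np.full(ns, default)
        for key, val in overrides.items():
            for s in states:
                if s == key or s.startswith(key):
                    v[s_idx[s]] = val
        return v

    def branch_vec(default: float, branch: str, val: float) -> np.ndarray:
        v = np.full(ns, default)
        for s in states:
            if lineage.states[s].region == branch:
                v[s_idx[s]] = val
        return v

    genes: list[GeneModel] = []
    expr = []          # rows follow genes
    gene_rows = []     # (gene_id, category, branch)
    peaks: dict[str, list[_PeakDesign]] = {m: [] for m in MARKS}
    biv_rows, swi_rows, primed_rows = [], [], []

    hi, mid, lo = emission.expr_high, emission.expr_mid, emission.expr_low
    pt_lo, pt_hi = 0.40, 1.00  # telencephalic neurogenesis span (NPC + neuron)
    bin_w = (pt_hi - pt_lo) / PRIMING_BINS

    gene_idx = 0
    for category, size in _CATEGORY_SIZES.items():
        for k in range(size):
            chrom, off = _gene_position(gene_idx)
            strand = "-" if gene_idx % 4 == 3 else "+"
            body = GenomicInterval(chrom, off, off + _GENE_BODY)
            gene = GeneModel(f"gene_{gene_idx:04d}", body, strand)
            genes.append(gene)
            tss = gene.tss
            prom = GenomicInterval(chrom, tss - _PEAK_HALF, tss + _PEAK_HALF)
            distal = GenomicInterval(chrom, tss + _DISTAL_OFFSET, tss + _DISTAL_OFFSET + 500)
            branch = BRANCHES[k % 4]
            gid = gene.gene_id

            def add(mark: str, interval: GenomicInterval, p: np.ndarray, role: str) -> None:
                peaks[mark].append(_PeakDesign(interval, np.clip(p, 0.0, 0.95), gid, role))

            if category == "housekeeping":
                e = vec(mid)
                add("H3K4me3", prom, vec(0.40), "housekeeping")
                add("H3K27ac", prom, vec(0.35), "housekeeping")
            elif category == "progenitor":
                # cycling/progenitor program: active through neuroepithelium
                # and NPC stages, H3K27me3-repressed as neurons are born
                cycling = np.array(
                    [s == "neuroepithelium" or s.endswith("_npc") for s in states]
                )
                neuron = np.array([s.endswith("_neuron") for s in states])
                e = np.where(cycling, hi, lo)
                add("H3K4me3", prom, np.where(cycling, 0.40, 0.03), "progenitor")
                add("H3K27ac", prom, np.where(cycling, 0.40, 0.03), "progenitor")
                add("H3K27me3", prom, np.where(neuron, 0.45, 0.02), "progenitor")
            elif category == "silent":
                # no expression, no marks: the inactive & unmarked census class
                e = vec(lo)
            elif category == "pluripotency":
                e = vec(lo, PSC=hi)
                add("H3K4me3", prom, vec(0.05, PSC=0.45), "program")
                add("H3K27ac", prom, vec(0.03, PSC=0.45), "program")
                # repressed outside pluripotency; promoter-located so the
                # anti-correlation shows up in H3K27me3 gene activity
                add("H3K27me3", prom, vec(0.35, PSC=0.02), "program")
            elif category == "neuroepithelial":
                e = vec(lo, neuroepithelium=hi)
                add("H3K4me3", prom, vec(0.05, neuroepithelium=0.45), "program")
                add("H3K27ac", prom, vec(0.03, neuroepithelium=0.45), "program")
                add("H3K27me3", prom, vec(0.35, PSC=0.30, neuroepithelium=0.02), "program")
            elif category == "repressed":
                e = vec(lo)
                add("H3K27me3", prom, vec(0.35), "repressed")
            elif category == "marker":
                # alternate pan-branch markers (NPC + neuron) and neuron-only
                # markers so progenitor and neuron states are separable
                if k % 8 < 4:
                    on = branch_vec(0.0, branch, 1.0)
                else:
                    on = np.array(
                        [1.0 if s == f"{branch}_neuron" else 0.0 for s in states]
                    )
                e = lo + (hi - lo) * on
                # silent (p = 0.01) at the PSC/NE stages so marker promoters
                # never enter the bivalent/switching candidate rules, even as
                # sampling noise at a few hundred NE cells
                early = np.array([s in ("PSC", "neuroepithelium") for s in states])
                ac = np.where(early, 0.01, 0.03 + 0.42 * on)
                k4 = np.where(early, 0.01, 0.03 + 0.37 * on)
                me3 = np.where(early, 0.01, 0.45 - 0.43 * on)
                add("H3K27ac", prom, ac, "marker")
                add("H3K4me3", prom, k4, "marker")
                add("H3K27me3", prom, me3, "marker")
            elif category == "bivalent":
                activated = k % 3 != 2  # mixture of resolutions, mostly activation
                if activated:
                    e = branch_vec(lo, branch, hi)
                    k4 = branch_vec(0.05, branch, 0.65)
                    me3 = branch_vec(0.50, branch, 0.02)
                else:
                    e = vec(lo)
                    k4 = branch_vec(0.40, branch, 0.02)
                    me3 = branch_vec(0.05, branch, 0.65)
                for v in (k4, me3):
                    v[s_idx["PSC"]] = 0.32
                    v[s_idx["neuroepithelium"]] = 0.35
                add("H3K4me3", prom, k4, "bivalent")
                add("H3K27me3", prom, me3, "bivalent")
                biv_rows.append(
                    dict(
                        gene_id=gid,
                        k4_peak=prom.peak_id,
                        me3_peak=prom.peak_id,
                        branch=branch,
                        resolution="activated" if activated else "repressed",
                    )
                )
            elif category == "decoy_bivalent_lowNE":
                # resolves like a bivalent pair but H3K27me3 is silent in NE:
                # must fail the >5% neuroepithelium co-detection rule
                e = branch_vec(lo, branch, hi)
                k4 = branch_vec(0.05, branch, 0.60)
                k4[s_idx["neuroepithelium"]] = 0.35
                k4[s_idx["PSC"]] = 0.30
                me3 = branch_vec(0.45, branch, 0.02)
                me3[s_idx["neuroepithelium"]] = 0.01
                me3[s_idx["PSC"]] = 0.01
                add("H3K4me3", prom, k4, "decoy_bivalent_lowNE")
                add("H3K27me3", prom, me3, "decoy_bivalent_lowNE")
            elif category == "decoy_bivalent_flat":
                # co-detected in NE but never resolves (no regional differential)
                e = vec(1.0)
                add("H3K4me3", prom, vec(0.35), "decoy_bivalent_flat")
                add("H3K27me3", prom, vec(0.30), "decoy_bivalent_flat")
            elif category == "switching":
                e = branch_vec(lo, branch, hi)
                me3 = branch_vec(0.45, branch, 0.02)
                me3[s_idx["PSC"]] = 0.40
                me3[s_idx["neuroepithelium"]] = 0.40
                ac = branch_vec(0.01, branch, 0.60)
                add("H3K27me3", prom, me3, "switching")
                add("H3K27ac", prom, ac, "switching")
                swi_rows.append(
                    dict(gene_id=gid, me3_peak=prom.peak_id, ac_peak=prom.peak_id, branch=branch)
                )
            elif category == "decoy_switch_both":
                # both marks detected in NE: bivalency territory, not switching
                e = vec(1.0)
                me3 = branch_vec(0.40, branch, 0.03)
                me3[s_idx["neuroepithelium"]] = 0.30
                ac = branch_vec(0.05, branch, 0.60)
                ac[s_idx["neuroepithelium"]] = 0.30
                add("H3K27me3", prom, me3, "decoy_switch_both")
                add("H3K27ac", prom, ac, "decoy_switch_both")
            elif category == "decoy_switch_flat":
                # repressed everywhere, no branch ever activates
                e = vec(lo)
                add("H3K27me3", prom, vec(0.40), "decoy_switch_flat")
                add("H3K27ac", prom, vec(0.01), "decoy_switch_flat")
            elif category == "primed":
                # telencephalic neuronal gene: H3K27ac turns on `lag` bins
                # before RNA along the 20-bin neurogenesis reference grid,
                # with onsets at the NPC -> neuron transition
                lag = k % 5 + 1
                chrom_bin = 11 + k % 4
                rna_bin = chrom_bin + lag
                e = vec(lo)
                ac = vec(0.05)
                add("H3K27ac", prom, ac, "primed")
                primed_rows.append(
                    dict(
                        gene_id=gid,
                        ac_peak=prom.peak_id,
                        lag_bins=lag,
                        chrom_bin=chrom_bin,
                        rna_bin=rna_bin,
                        chrom_onset=pt_lo + (chrom_bin - 1) * bin_w,
                        rna_onset=pt_lo + (rna_bin - 1) * bin_w,
                    )
                )
            else:  # pragma: no cover
                raise AssertionError(category)

            expr.append(e)
            gene_rows.append(dict(gene_id=gid, category=category, branch=branch))
            gene_idx += 1

    # fill peaks: state-constant detection, mark-specific genomic zones so they
    # never overlap each other or gene-proximal peaks across marks
    for mi, mark in enumerate(MARKS):
        n = n_fill[mark]
        p_fill = np.clip(rng.beta(1.2, 14.0, size=n), 0.005, 0.4)
        for j in range(n):
            start = 100_000 + (3 * j + mi) * 6_000
            iv = GenomicInterval("chr9", start, start + 500)
            peaks[mark].append(_PeakDesign(iv, np.full(ns, p_fill[j]), None, "fill"))

    return genes, np.asarray(expr), pd.DataFrame(gene_rows), peaks, biv_rows, swi_rows, primed_rows


def _census_class(
    gene_id: str,
    expr_row: np.ndarray,
    peaks: dict[str, list[_PeakDesign]],
    emission: EmissionSpec,
    category: str,
) -> str:
    """Four-way census class implied by the planted design (detectable means
    planted probability > 0.05 in some state)."""
    # primed genes switch on within the telencephalic branch (pt-dependent
    # emission), which the static design matrix does not show
    active = bool(expr_row.max() >= emission.expr_mid) or category == "primed"
    repressed = False
    for mark in MARKS:
        for pk in peaks[mark]:
            if pk.gene_id != gene_id:
                continue
            if pk.p.max() > 0.05:
                if mark == "H3K27me3":
                    repressed = True
                else:
                    active = True
    if active and repressed:
        return "active_and_repressed"
    if active:
        return "always_active"
    if repressed:
        return "inactive_and_repressed"
    return "inactive_unmarked"


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

_BLEND_FRACTION = 0.6  # fraction of a state's pseudotime span spent ramping in


def _blend_weights(lineage: LineageSpec, state: str, pt: np.ndarray) -> np.ndarray:
    """Weight of the state's own profile vs its parent's, as a function of
    pseudotime within the state: cells enter with the parent's profile and
    ramp to their own over the first part of the state's span, so expression
    and chromatin form a continuum along the lineage rather than discrete
    blocks."""
    spec = lineage.states[state]
    if spec.parent is None:
        return np.ones_like(pt)
    lo, hi = spec.pt_range
    span = max(hi - lo, 1e-9) * _BLEND_FRACTION
    return np.clip((pt - lo) / span, 0.0, 1.0)


def _sample_cells(lineage: LineageSpec, modality: str, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for spec in lineage.states.values():
        pt = rng.uniform(*spec.pt_range, size=spec.n_cells)
        for t in pt:
            rows.append(
                dict(
                    modality=modality,
                    state=spec.name,
                    region=spec.region,
                    stage=spec.stage,
                    timepoint=spec.timepoint,
                    pseudotime=float(t),
                )
            )
    cells = pd.DataFrame(rows)
    cells.insert(0, "cell_id", [f"{modality}_{i:05d}" for i in range(len(cells))])
    cells["line"] = np.where(np.arange(len(cells)) % 2 == 0, "L1", "L2")
    cells["condition"] = "control"
    return cells


def binomial_detection_counts(
    p: np.ndarray, depth_factor: np.ndarray, trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Fragment counts ~ Binomial(trials, q) with q chosen so that
    P(count > 0) = 1 - (1 - p)^depth_factor."""
    # q per (cell, peak): 1 - (1-p)^(s/trials)
    log1m = np.log1p(-np.minimum(p, 0.999999))[None, :]
    q = 1.0 - np.exp(log1m * (depth_factor[:, None] / trials))
    return rng.binomial(trials, q)


def _simulate_chromatin(
    mark: str,
    cells: pd.DataFrame,
    designs: list[_PeakDesign],
    lineage: LineageSpec,
    emission: EmissionSpec,
    primed_truth: list[dict],
    rng: np.random.Generator,
) -> CountMatrix:
    state_index = {s: i for i, s in enumerate(lineage.state_names)}
    p_matrix = np.stack([d.p for d in designs], axis=0)  # peaks x states
    depth = np.exp(rng.normal(0.0, emission.depth_sigma, size=len(cells)))
    peak_pos = {d.interval.peak_id: j for j, d in enumerate(designs)}

    blocks = []
    row_order = []
    for state, grp in cells.groupby("state", sort=False):
        idx = grp.index.to_numpy()
        pt_cells = grp["pseudotime"].to_numpy()
        w = _blend_weights(lineage, state, pt_cells)
        own = p_matrix[:, state_index[state]]
        parent = lineage.states[state].parent
        base = p_matrix[:, state_index[parent]] if parent else own
        p_cells = (1 - w)[:, None] * base[None, :] + w[:, None] * own[None, :]
        if mark == "H3K27ac" and lineage.states[state].region == "telencephalon":
            # primed peaks: step from low to high detection at the planted onset
            pt = grp["pseudotime"].to_numpy()
            for row in primed_truth:
                j = peak_pos.get(row["ac_peak"])
                if j is not None:
                    p_cells[:, j] = np.where(pt >= row["chrom_onset"], 0.60, 0.05)
        counts = binomial_detection_counts_rows(p_cells, depth[idx], emission.trials, rng)
        blocks.append(sp.csr_matrix(counts))
        row_order.append(idx)
    order = np.concatenate(row_order)
    mat = sp.vstack(blocks).tocsr()[np.argsort(order)]
    return CountMatrix(
        mat, cells["cell_id"].tolist(), [d.interval.peak_id for d in designs], mark
    )


def binomial_detection_counts_rows(
    p_cells: np.ndarray, depth_factor: np.ndarray, trials: int, rng: np.random.Generator
) -> np.ndarray:
    log1m = np.log1p(-np.minimum(p_cells, 0.999999))
    q = 1.0 - np.exp(log1m * (depth_factor[:, None] / trials))
    return rng.binomial(trials, q)


def _simulate_rna(
    cells: pd.DataFrame,
    expr: np.ndarray,
    genes: list[GeneModel],
    gene_table: pd.DataFrame,
    lineage: LineageSpec,
    emission: EmissionSpec,
    primed_truth: list[dict],
    rng: np.random.Generator,
) -> CountMatrix:
    state_index = {s: i for i, s in enumerate(lineage.state_names)}
    gene_pos = {g: i for i, g in enumerate(gene_table["gene_id"])}
    depth = np.exp(rng.normal(0.0, emission.depth_sigma, size=len(cells)))

    blocks = []
    row_order = []
    for state, grp in cells.groupby("state", sort=False):
        idx = grp.index.to_numpy()
        pt_cells = grp["pseudotime"].to_numpy()
        w = _blend_weights(lineage, state, pt_cells)
        own = expr[:, state_index[state]]
        parent = lineage.states[state].parent
        base = expr[:, state_index[parent]] if parent else own
        means = (1 - w)[:, None] * base[None, :] + w[:, None] * own[None, :]
        if lineage.states[state].region == "telencephalon":
            pt = grp["pseudotime"].to_numpy()
            for row in primed_truth:
                j = gene_pos[row["gene_id"]]
                means[:, j] = np.where(pt >= row["rna_onset"], emission.expr_high, emission.expr_low)
        means *= depth[idx][:, None]
        r = emission.rna_dispersion
        lam = rng.gamma(shape=r, scale=means / r)
        counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts))
        row_order.append(idx)
    order = np.concatenate(row_order)
    mat = sp.vstack(blocks).tocsr()[np.argsort(order)]
    return CountMatrix(mat, cells["cell_id"].tolist(), [g.gene_id for g in genes], "RNA")


def simulate_dataset(
    lineage: LineageSpec | None = None,
    emission: EmissionSpec | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate the full multi-modal dataset with planted truth.

    Same seed gives identical output. Default scale: ~2,570 cells per
    modality, 3,000 peaks per histone mark, 2,000 genes.
    """
    lineage = lineage or default_lineage()
    emission = emission or EmissionSpec()
    rng = np.random.default_rng(seed)

    n_designed = {
        "H3K27ac": 550 + 100 + 100 + 100 + 400 + 50 + 50 + 25 + 100,
        "H3K4me3": 550 + 100 + 100 + 100 + 400 + 50 + 50 + 50,
        "H3K27me3": 100 + 100 + 100 + 300 + 400 + 50 + 50 + 50 + 50 + 50 + 25,
    }
    n_fill = {m: 3000 - n for m, n in n_designed.items()}
    genes, expr, gene_table, peak_designs, biv_rows, swi_rows, primed_rows = (
        _design_genes_and_peaks(lineage, emission, n_fill, rng)
    )

    gene_table["census_class"] = [
        _census_class(row.gene_id, expr[i], peak_designs, emission, row.category)
        for i, row in enumerate(gene_table.itertuples())
    ]

    counts: dict[str, CountMatrix] = {}
    all_cells = []
    rna_cells = _sample_cells(lineage, "RNA", rng)
    counts["RNA"] = _simulate_rna(
        rna_cells, expr, genes, gene_table, lineage, emission, primed_rows, rng
    )
    all_cells.append(rna_cells)
    for mark in MARKS:
        cells = _sample_cells(lineage, mark, rng)
        counts[mark] = _simulate_chromatin(
            mark, cells, peak_designs[mark], lineage, emission, primed_rows, rng
        )
        all_cells.append(cells)

    cells = pd.concat(all_cells, ignore_index=True)
    branch_of = dict(zip(gene_table["gene_id"], gene_table["branch"]))
    marker_rows = [
        dict(peak_id=d.interval.peak_id, modality=mark, branch=branch_of[d.gene_id])
        for mark in MARKS
        for d in peak_designs[mark]
        if d.role == "marker"
    ]
    truth = SyntheticTruth(
        cells=cells,
        bivalent=pd.DataFrame(biv_rows),
        switching=pd.DataFrame(swi_rows),
        primed=pd.DataFrame(primed_rows),
        gene_classes=gene_table[["gene_id", "category", "census_class"]].copy(),
        marker_peaks=pd.DataFrame(marker_rows),
    )
    metadata = cells[["cell_id", "modality", "timepoint", "line", "condition"]].rename(
        columns={"timepoint": "timepoint_group"}
    )
    peaks = {m: [d.interval for d in peak_designs[m]] for m in MARKS}
    for mark in MARKS:
        med = float(np.median(counts[mark].cell_totals()))
        logger.info("%s: %d cells, median %d fragments per cell", mark, counts[mark].n_cells, med)
    return SyntheticDataset(counts, metadata, peaks, genes, truth, lineage, emission)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path, force: bool = False) -> dict:
    """Write a dataset in the genomic_io formats plus truth tables.

    Returns a manifest mapping logical names to file paths (also written as
    manifest.json).
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for modality, cm in dataset.counts.items():
        paths = {
            f"{modality}_matrix": out / f"{modality}_matrix.mtx",
            f"{modality}_features": out / f"{modality}_features.tsv",
            f"{modality}_barcodes": out / f"{modality}_barcodes.tsv",
        }
        write_mtx_triplet(
            cm,
            paths[f"{modality}_matrix"],
            paths[f"{modality}_features"],
            paths[f"{modality}_barcodes"],
        )
        manifest.update({k: str(v) for k, v in paths.items()})
    for mark, intervals in dataset.peaks.items():
        path = out / f"peaks_{mark}.bed"
        write_peak_bed(intervals, path)
        manifest[f"peaks_{mark}"] = str(path)
    write_gene_models(dataset.genes, out / "genes.tsv")
    manifest["genes"] = str(out / "genes.tsv")
    dataset.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    manifest["metadata"] = str(out / "metadata.tsv")
    truth = dataset.truth
    for name in ("cells", "bivalent", "switching", "primed", "gene_classes", "marker_peaks"):
        path = out / f"truth_{name}.tsv"
        getattr(truth, name).to_csv(path, sep="\t", index=False)
        manifest[f"truth_{name}"] = str(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest"] = str(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# focused generators for individual statistical procedures
# ---------------------------------------------------------------------------

def simulate_priming_bins(
    n_primed: int = 100,
    n_null: int = 100,
    n_bins: int = 20,
    cells_per_bin: int = 150,
    lags: tuple[int, ...] = (1, 2, 3, 4, 5),
    d_low: float = 0.05,
    d_high: float = 0.6,
    seed: int = 0,
) -> dict:
    """Binned detection data with planted chromatin-before-RNA lags.

    Primed features step from d_low to d_high detection at a planted chromatin
    bin, and in RNA `lag` bins later; null features stay at d_low in both.
    Returns binary cells x features matrices per modality, the per-cell bin
    assignment, per-cell fragment totals, and the truth table.
    """
    rng = np.random.default_rng(seed)
    n_cells = n_bins * cells_per_bin
    bins = np.repeat(np.arange(1, n_bins + 1), cells_per_bin)
    truth = []
    onset_rna = np.full(n_primed + n_null, n_bins + 1)
    onset_chrom = np.full(n_primed + n_null, n_bins + 1)
    for i in range(n_primed):
        lag = lags[i % len(lags)]
        chrom_bin = int(rng.integers(3, n_bins - max(lags)))
        onset_chrom[i] = chrom_bin
        onset_rna[i] = chrom_bin + lag
        truth.append(dict(feature=f"feat_{i:04d}", kind="primed", lag=lag,
                          chrom_bin=chrom_bin, rna_bin=chrom_bin + lag))
    for i in range(n_primed, n_primed + n_null):
        truth.append(dict(feature=f"feat_{i:04d}", kind="null", lag=np.nan,
                          chrom_bin=np.nan, rna_bin=np.nan))

    p_chrom = np.where(bins[:, None] >= onset_chrom[None, :], d_high, d_low)
    p_rna = np.where(bins[:, None] >= onset_rna[None, :], d_high, d_low)
    y_chrom = (rng.random((n_cells, n_primed + n_null)) < p_chrom).astype(np.int8)
    y_rna = (rng.random((n_cells, n_primed + n_null)) < p_rna).astype(np.int8)
    features = [t["feature"] for t in truth]
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    n_fragments = np.round(500 * np.exp(rng.normal(0, 0.3, n_cells))).astype(int)
    return dict(
        chromatin=pd.DataFrame(y_chrom, index=cell_ids, columns=features),
        rna=pd.DataFrame(y_rna, index=cell_ids, columns=features),
        bins=pd.Series(bins, index=cell_ids, name="bin"),
        n_fragments=pd.Series(n_fragments, index=cell_ids, name="n_fragments"),
        truth=pd.DataFrame(truth),
    )


def simulate_null_binary_peaks(
    n_peaks: int = 1000, n_cells: int = 400, seed: int = 0
) -> dict:
    """Depth-dependent binary detection with no group effect: the null for
    calibrating the binomial-GLM likelihood-ratio test."""
    rng = np.random.default_rng(seed)
    depth_factor = np.exp(rng.normal(0, 0.35, n_cells))
    p = rng.uniform(0.05, 0.5, n_peaks)
    q = 1.0 - np.exp(np.log1p(-p)[None, :] * depth_factor[:, None])
    y = (rng.random((n_cells, n_peaks)) < q).astype(np.int8)
    groups = np.array(["A", "B"])[rng.integers(0, 2, n_cells)]
    n_fragments = np.round(500 * depth_factor).astype(int)
    return dict(
        Y=pd.DataFrame(y, columns=[f"peak_{i:04d}" for i in range(n_peaks)]),
        group=pd.Series(groups, name="group"),
        n_fragments=pd.Series(n_fragments, name="n_fragments"),
    )


def simulate_composition(
    n_per_stratum: int = 400,
    n_clusters: int = 5,
    n_strata: int = 3,
    enriched_cluster: int = 0,
    odds_ratio: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Treated/control cells over clusters and sampling-timepoint strata, with
    one cluster enriched among treated cells at a planted odds ratio."""
    rng = np.random.default_rng(seed)
    base = np.full(n_clusters, 1.0 / n_clusters)
    rows = []
    for s in range(n_strata):
        for cond in ("control", "treated"):
            w = base.copy()
            if cond == "treated":
                # scale the enriched cluster's one-vs-rest odds by odds_ratio
                # exactly, spreading the remaining mass proportionally
                w0 = w[enriched_cluster]
                odds0 = odds_ratio * w0 / (1 - w0)
                w0_new = odds0 / (1 + odds0)
                w *= (1 - w0_new) / (1 - w0)
                w[enriched_cluster] = w0_new
            labels = rng.choice(n_clusters, size=n_per_stratum, p=w)
            rows.append(
                pd.DataFrame(
                    dict(cluster=labels, condition=cond, stratum=f"t{s}")
                )
            )
    df = pd.concat(rows, ignore_index=True)
    df.insert(0, "cell_id", [f"cell_{i:05d}" for i in range(len(df))])
    return df


def simulate_perturbation_expression(
    n_genes: int = 200,
    n_de: int = 20,
    n_cells_per_condition: int = 400,
    effect: float = 2.0,
    seed: int = 0,
) -> dict:
    """Binarized expression for the perturbation DE arm: the first ``n_de``
    genes have an ``effect``-fold higher detection rate in treated cells."""
    rng = np.random.default_rng(seed)
    n_cells = 2 * n_cells_per_condition
    condition = np.array(["control"] * n_cells_per_condition + ["treated"] * n_cells_per_condition)
    base = rng.uniform(0.05, 0.3, n_genes)
    p = np.tile(base, (n_cells, 1))
    p[condition == "treated", :n_de] = np.minimum(base[:n_de] * effect, 0.9)
    y = (rng.random((n_cells, n_genes)) < p).astype(np.int8)
    covars = pd.DataFrame(
        dict(
            n_umi=np.round(4000 * np.exp(rng.normal(0, 0.3, n_cells))).astype(int),
            timepoint=rng.choice(["d15", "d18"], n_cells),
            cluster=rng.choice(["c0", "c1", "c2"], n_cells),
        )
    )
    return dict(
        Y=pd.DataFrame(y, columns=[f"gene_{i:04d}" for i in range(n_genes)]),
        condition=pd.Series(condition, name="condition"),
        covariates=covars,
        de_genes=[f"gene_{i:04d}" for i in range(n_de)],
    )
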