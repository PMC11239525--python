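"""Readers/writers for the standard formats the pipeline touches, plus interval
arithmetic shared by all stages.

All coordinates are 0-based, half-open (BED native). Any 1-based external table
must be converted at the boundary. Peak identifiers are canonicalized as
``chrom:start-end`` so count matrices and interval lists can be joined by id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

CHROMATIN_MODALITIES = ("H3K27ac", "H3K27me3", "H3K4me3", "ATAC")
MODALITIES = ("RNA",) + CHROMATIN_MODALITIES


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def peak_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def extended(self, slop: int) -> "GenomicInterval":
        """Extend by ``slop`` bp on both sides, clamping the start at 0."""
        return GenomicInterval(self.chrom, max(0, self.start - slop), self.end + slop, self.name)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def parse_peak_id(peak_id: str, name: str | None = None) -> GenomicInterval:
    chrom, _, coords = peak_id.rpartition(":")
    start, _, end = coords.partition("-")
    return GenomicInterval(chrom, int(start), int(end), name)


@dataclass(frozen=True)
class GeneModel:
    """Gene body with strand and transcription start site.

    The TSS is the 0-based coordinate of the first transcribed base:
    ``body.start`` on the plus strand, ``body.end - 1`` on the minus strand.
    """

    gene_id: str
    body: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1

    def activity_window(self, upstream: int = 2000) -> GenomicInterval:
        """Gene body extended ``upstream`` bp on the promoter (strand) side."""
        if self.strand == "+":
            return GenomicInterval(
                self.body.chrom, max(0, self.body.start - upstream), self.body.end, self.gene_id
            )
        return GenomicInterval(
            self.body.chrom, self.body.start, self.body.end + upstream, self.gene_id
        )


@dataclass
class CountMatrix:
    """Sparse cells x features matrix of non-negative integer counts."""

    values: sp.csr_matrix
    cell_ids: list[str]
    feature_ids: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        n, m = self.values.shape
        if n != len(self.cell_ids):
            raise ValueError(f"{n} rows but {len(self.cell_ids)} cell ids")
        if m != len(self.feature_ids):
            raise ValueError(f"{m} columns but {len(self.feature_ids)} feature ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def subset_cells(self, cell_ids: Sequence[str]) -> "CountMatrix":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        rows = [index[c] for c in cell_ids]
        return CountMatrix(self.values[rows], list(cell_ids), list(self.feature_ids), self.modality)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_peak_bed(path: str | Path) -> list[GenomicInterval]:
    """Read peak intervals from a BED file (3+ tab-separated columns)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}, line {lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: non-numeric coordinates") from exc
            name = parts[3] if len(parts) > 3 else None
            try:
                intervals.append(GenomicInterval(parts[0], start, end, name))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return intervals


def write_peak_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                fields.append(iv.name)
            fh.write("\t".join(fields) + "\n")


def read_mtx_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    modality: str = "RNA",
) -> CountMatrix:
    """Read a 10x-style triplet: MatrixMarket (features x cells) + id lists."""
    mat = scipy.io.mmread(matrix_path)
    features = _read_id_list(features_path)
    barcodes = _read_id_list(barcodes_path)
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix is {mat.shape} but got {len(features)} features and {len(barcodes)} barcodes"
        )
    mat = sp.csr_matrix(mat.T)
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("negative entries in count matrix")
    mat.data = np.round(mat.data).astype(np.int64)
    return CountMatrix(mat, barcodes, features, modality)


def write_mtx_triplet(
    counts: CountMatrix,
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(counts.values.T), field="integer")
    _write_id_list(counts.feature_ids, features_path)
    _write_id_list(counts.cell_ids, barcodes_path)


def _read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_id_list(ids: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.writelines(f"{i}\n" for i in ids)


FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read a 10x-dialect fragments file; rows sorted by (chrom, start)."""
    frags = pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLUMNS, comment="#")
    if (frags["count"] < 1).any():
        bad = int((frags["count"] < 1).sum())
        raise ValueError(f"{bad} fragment rows with count < 1")
    if (frags["start"] >= frags["end"]).any():
        raise ValueError("fragment rows with start >= end")
    return frags.sort_values(["chrom", "start", "end", "barcode"], kind="mergesort").reset_index(
        drop=True
    )


def write_fragments(frags: pd.DataFrame, path: str | Path) -> None:
    frags[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a TSV with header (gene_id, chrom, start, end, strand)."""
    table = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"gene model table missing columns: {sorted(missing)}")
    return [
        GeneModel(row.gene_id, GenomicInterval(row.chrom, int(row.start), int(row.end)), row.strand)
        for row in table.itertuples()
    ]


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.body.chrom, g.body.start, g.body.end, g.strand) for g in genes],
        columns=GENE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def intersect_intervals(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    slop: int = 0,
) -> list[tuple[int, int]]:
    """All index pairs (i, j) where a[i] and b[j] overlap after extending both
    by ``slop`` bp on each side (starts clamped at 0), on the same chromosome.

    Each qualifying pair is reported exactly once, sorted by (i, j).
    """
    if slop < 0:
        raise ValueError("slop must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(b):
        ext = iv.extended(slop)
        trees.setdefault(ext.chrom, IntervalTree()).addi(ext.start, ext.end, j)
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        ext = iv.extended(slop)
        pairs.extend((i, hit.data) for hit in tree.overlap(ext.start, ext.end))
    pairs.sort()
    return pairs


def merge_intervals(intervals: Sequence[GenomicInterval], slop: int = 0) -> list[list[int]]:
    """Group intervals into connected components of the (slop-extended) overlap
    graph; returns lists of member indices, each sorted, in genomic order."""
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start))
    groups: list[list[int]] = []
    cur_chrom, cur_end = None, -1
    for idx in order:
        iv = intervals[idx].extended(slop)
        if iv.chrom != cur_chrom or iv.start >= cur_end:
            groups.append([idx])
            cur_chrom, cur_end = iv.chrom, iv.end
        else:
            groups[-1].append(idx)
            cur_end = max(cur_end, iv.end)
    return [sorted(g) for g in groups]


def span_interval(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    """Union span of same-chromosome intervals."""
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) != 1:
        raise ValueError("intervals span multiple chromosomes")
    return GenomicInterval(
        chroms.pop(), min(iv.start for iv in intervals), max(iv.end for iv in intervals)
    )


def interval_gene_distance(iv: GenomicInterval, gene: GeneModel) -> int:
    """Distance in bp between an interval and a gene body (0 if overlapping)."""
    if iv.chrom != gene.body.chrom:
        return np.iinfo(np.int64).max
    if iv.overlaps(gene.body):
        return 0
    if iv.end <= gene.body.start:
        return gene.body.start - iv.end
    return iv.start - gene.body.end


def interval_tss_distance(iv: GenomicInterval, gene: GeneModel) -> int:
    """Distance in bp between an interval and a gene's TSS (0 if inside)."""
    if iv.chrom != gene.body.chrom:
        return np.iinfo(np.int64).max
    if iv.start <= gene.tss < iv.end:
        return 0
    if gene.tss < iv.start:
        return iv.start - gene.tss
    return gene.tss - (iv.end - 1)
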