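#!/usr/bin/env python
"""Regional differential peaks, bivalent and switching domain calls scored
against the planted truth, locus classification and the four-way gene
census."""

from pathlib import Path

import numpy as np
import pandas as pd

from epistate.genomic_io import parse_peak_id
from epistate.pipeline import domain_calls
from epistate.states import classify_locus, gene_regulatory_census
from epistate.synthetic import simulate_dataset

SEED = 7
ROOT = Path(__file__).resolve().parents[1]


def census(ds) -> pd.Series:
    truth = ds.truth.cells.set_index("cell_id")
    detection = {}
    for modality in ("RNA", "H3K27ac", "H3K4me3", "H3K27me3"):
        cm = ds.counts[modality]
        states = truth.loc[cm.cell_ids, "state"]
        Y = (cm.values > 0).astype(float)
        rates = pd.DataFrame(
            {s: np.asarray(Y[(states == s).to_numpy()].mean(axis=0)).ravel()
             for s in states.unique()},
            index=cm.feature_ids,
        )
        if modality == "RNA":
            rates.index = [g.gene_id for g in ds.genes]
        else:
            from epistate.genomic_io import intersect_intervals

            peaks = [parse_peak_id(p) for p in cm.feature_ids]
            windows = [g.activity_window(2_000) for g in ds.genes]
            per_gene: dict[str, np.ndarray] = {}
            for i, j in intersect_intervals(peaks, windows, slop=0):
                gid = ds.genes[j].gene_id
                per_gene[gid] = np.maximum(per_gene.get(gid, 0.0), rates.iloc[i].to_numpy())
            rates = pd.DataFrame(per_gene, index=rates.columns).T
        detection[modality] = rates
    classes, fractions = gene_regulatory_census(detection)
    return pd.Series(fractions).sort_values(ascending=False)


def main() -> None:
    ds = simulate_dataset(seed=SEED)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    dc = domain_calls(ds, seed=0)
    dc["bivalent"].to_csv(results / "05_bivalent_calls.tsv", sep="\t", index=False)
    dc["switching"].to_csv(results / "05_switching_calls.tsv", sep="\t", index=False)
    print("bivalent:", dc["bivalent_score"])
    print("switching:", dc["switching_score"])

    peaks = [parse_peak_id(p) for p in ds.counts["H3K4me3"].feature_ids]
    locus = classify_locus(peaks, ds.genes)
    locus.value_counts().to_csv(results / "05_locus_classes.tsv", sep="\t")
    print("\nH3K4me3 locus classes:\n", locus.value_counts().to_string())

    frac = census(ds)
    frac.rename("fraction").to_csv(results / "05_gene_census.tsv", sep="\t")
    print("\ngene census:\n", (100 * frac).round(1).to_string())


if __name__ == "__main__":
    main()
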