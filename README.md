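# epistate

Analysis pipeline for single-cell histone-modification dynamics along
developmental lineages, built around the computational procedures used to
study neural-organoid development with single-cell CUT&Tag (H3K27ac,
H3K4me3, H3K27me3) alongside scRNA-seq. Because each histone mark is
profiled in its own cells, nothing links the modalities except statistical
structure — this package implements the bespoke machinery that makes the
joint analysis possible, and a synthetic-data generator with planted ground
truth so every stage is testable without any data download.

It is aimed at computational biologists who want a tested, reusable
implementation of these procedures:

- **Cross-modality cluster matching.** High-resolution chromatin clusters
  are matched to RNA clusters by minimum-cost maximum-flow (MCMF) on a
  sparsified bipartite graph whose edge costs are correlation distances
  between mean gene-activity and expression profiles, `d = 1 − r` for
  activating marks and `d = 1 + r` for the repressive mark H3K27me3; a null
  node priced at the 99th cost percentile absorbs unmatchable clusters,
  which then fall back to their minimum-cost counterpart.
- **Terminal-fate probabilities and trajectory graphs.** A forward-biased
  kernel on the kNN graph (edge weight ∝ exp(β·(t(v) − t(u))) for
  pseudotime t) defines an absorbing Markov chain whose absorption
  probabilities f<sub>it</sub> (cell i, terminal state t, Σ<sub>t</sub>
  f<sub>it</sub> = 1) are solved exactly via the fundamental matrix. A
  kNN graph over cluster-mean fate vectors, pruned to edges forward in
  pseudotime and within one regional branch, gives the coarse trajectory
  graph; the circular projection x<sub>i</sub> = Σ<sub>t</sub>
  f<sub>it</sub> cos α<sub>t</sub>, y<sub>i</sub> = Σ<sub>t</sub>
  f<sub>it</sub> sin α<sub>t</sub> places cells among evenly spaced
  terminal states.
- **Differential detection and chromatin domains.** Binarized peak counts
  are tested with a binomial GLM (logit link), `Y ~ n_fragments + group`
  versus `Y ~ n_fragments`, by likelihood-ratio test with BH correction.
  Bivalent domains are H3K4me3/H3K27me3 peak pairs overlapping after ±2 kb
  extension, co-detected (>5% of cells) in a neuroepithelium-stage cluster
  and resolving with opposite-sign regional enrichment; switching domains
  are H3K27me3/H3K27ac pairs with exactly one mark detected at that stage
  and an activation branch where the silent mark turns on as the other is
  depleted.
- **Pseudotemporal dynamics and epigenetic priming.** Cells are stratified
  into equal-occupancy pseudotime bins; profiles are smoothed with cubic
  smoothing splines (GCV), clustered by dynamic-time-warping distance with
  k-medoids, and each gene's *first divergent bin* (first bin with
  FDR < 0.05 and |log2 detection fold change| > 0.25 versus bin 1) is
  computed per modality. The **pseudotime lag** — RNA bin minus chromatin
  bin — quantifies how far chromatin activation precedes expression.
- **Perturbation statistics.** Stratified Cochran–Mantel–Haenszel tests for
  composition shifts, logistic-regression differential expression with the
  treatment as the response (`treatment ~ Y_gene + n_UMI + timepoint +
  cluster`), Fisher-exact motif enrichment, and bulk peak log2 fold
  changes.

## Worked example

```python
from epistate.synthetic import simulate_dataset
from epistate.pipeline import match_modalities, domain_calls

ds = simulate_dataset(seed=7)          # ~2,570 cells/modality, 3,000 peaks/mark
results = match_modalities(ds, seed=0)
for mark, res in results.items():
    print(mark, round(res["accuracy"], 3))
dc = domain_calls(ds, seed=0)
print(dc["bivalent_score"], dc["switching_score"])
```

prints

```
H3K27ac 1.0
H3K4me3 0.917
H3K27me3 1.0
{'n_called': 51, 'precision': 0.9803921568627451, 'recall': 1.0} {'n_called': 50, 'precision': 1.0, 'recall': 1.0}
```

i.e. after QC, TF-IDF/LSI embedding, per-timepoint clustering, gene-activity
scoring and MCMF matching, ≥ 92% of chromatin clusters per mark inherit the
annotation of the RNA state that generated them (including the
anti-correlated repressive mark), and the bivalent/switching callers recover
the 50 planted domains of each kind at ≥ 0.98 precision and 1.0 recall.

The numbered drivers under `analysis/` run the full study arc —
`01_simulate_data.py` through `07_perturbation.py` — writing small summary
tables to `results/` (the full simulated dataset goes to `scratch/`).

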