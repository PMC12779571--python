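# heteroclust

Analytics for **heterotypic CD8 T cell clusters** — physical conjugates of a
CD8 T cell with a tumour cell and/or an antigen-presenting cell (APC) that
survive tissue dissociation and appear as double-positive events in flow
cytometry. Such clusters are enriched for tumour-reactive T cells, yet a
standard scatter singlet gate silently discards them. This package provides
reusable, tested implementations of the computational procedures needed to
quantify that biology, for immunologists and computational biologists working
with co-culture flow data, imaging flow cytometry, multiplex
immunofluorescence, and paired scRNA-seq/scTCR-seq:

- **`cytocompete`** — threshold gating of T / tumour / cluster populations;
  the cluster-over-singlet fold enrichment of antigen-specific T cells,
  FC = (specific fraction in clusters) / (specific fraction in singlets),
  with a percentile-bootstrap CI; and the fraction of clustered events lost
  to a robust area-vs-height singlet gate.
- **`imagesynapse`** — imaging-flow-cytometry synapse scoring: variance-filter
  (radius 2 px) segmentation inputs, watershed (or plug-in) segmentation with
  2-px label contraction, k-means cell typing on channel means + area, 1:1
  heterotypic doublet extraction, and interface vs non-interface membrane
  means (outer 3 px membrane) with a paired Wilcoxon test.
- **`spatialprox`** — multiplex-IF marker reclassification and the 10-µm
  nearest-neighbour definition of T–tumour and T–APC clusters (tumour
  proximity takes precedence; the cutoff is strict).
- **`scquant`** — single-cell QC (200–8,000 detected genes, ≤15%
  mitochondrial), density-local-minimum hashtag demultiplexing,
  equal-patient-weighted state frequencies, a binomial random-intercept GLMM
  (logit P(state) = β₀ + β₁·cluster + u_patient, Gauss–Hermite ML, Wald test,
  Bonferroni) with a stratified permutation oracle, 10-nearest-neighbour
  smoothed CD39 calls, and paired α/β clonotype analytics.
- **`signature`** — cluster-vs-singlet differential expression (Wilcoxon
  default, plug-in slot), top-30/top-100 signature construction
  (−log₁₀ p_adj > 150, expressed in >30% of cluster cells, ordered by
  log₂FC), per-cell ranking-AUC scores, and tertile responder stratification.
- **`lrnet`** — ligand–receptor curation (weight > 0.75, provenance branches,
  membrane/surface receptor localization), 10%/35% expression filters, and
  mean + 1 SD exclusivity assignment of genes to merged T-state subgroups.
- **`synthdata`** — generators for all of the above with planted ground
  truth (competition event tables, touching-doublet images, centroid fields,
  negative-binomial single-cell datasets with patients as batches, power-law
  clonotypes and bimodal hashtags, ligand–receptor tables), so every pipeline
  is testable without access to patient data.

## Worked example

```python
import heteroclust as hc
from heteroclust.cytocompete import fold_enrichment

thresholds = {"t_label": 100.0, "tumour_label": 100.0, "specific_marker": 100.0}
events, truth = hc.gen_competition_events(
    n_tumour=50_000, n_t=50_000, input_specific_fraction=0.40,
    planted_fold_change=2.7, cluster_fraction=0.20, seed=1)
est = fold_enrichment(events, thresholds, n_boot=1000, seed=1)
print(f"{est.fold_change:.2f}  ({est.ci_low:.2f}-{est.ci_high:.2f})")
```

prints

```
2.50  (2.47-2.53)
```

the estimated fold enrichment of antigen-specific T cells in heterotypic
clusters over singlets, with its bootstrap CI. (At a 40% specific input the
clustered specificity probability saturates at 1, so the observable fold
change is capped at 1/0.40 = 2.5; at a 1% input the same pipeline recovers an
11-fold planted enrichment essentially exactly.) The scripts in `examples/`
walk through each capability the same way — synapse relocalization scoring,
spatial proximity classification, state-enrichment GLMMs, signature
construction and AUC scoring, and ligand–receptor curation — each printing
the quantities it computes and a line on how to read them.

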