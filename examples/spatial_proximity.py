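"""Heterotypic-cluster classification from multiplex-IF centroids.

Generates a tissue field of tumour (SOX10/HMB45+), CD8 and CD11c (APC)
centroids in which 30% of CD8 T cells sit within 10 um of a tumour or APC
cell, applies the marker reclassification rules for double/triple positives,
and labels each CD8 cell by nearest-neighbour proximity: closer than 10 um to
a tumour cell makes a T-tumour cluster (taking precedence over APCs), else
closer than 10 um to a CD11c cell makes a T-APC cluster.
"""

import heteroclust as hc
from heteroclust.spatialprox import classify_proximity_clusters, reclassify_cells

table = hc.gen_centroid_table(
    n_cells=3000, niche_fraction=0.30, field_size_um=(1500.0, 1500.0), seed=1)
table = reclassify_cells(table)
labelled, summary = classify_proximity_clusters(table, cutoff_um=10.0)

print(f"CD8 cells analysed : {summary['n_cd8']}")
for lab, frac in summary["fractions"].items():
    print(f"  {lab:<14}: {100 * frac:5.1f}%  ({summary['counts'][lab]} cells)")

cd8 = labelled[labelled.final_class == "CD8"]
agreement = (cd8.cluster_label == cd8.truth_cluster).mean()
print(f"agreement with planted niche labels: {100 * agreement:.1f}%")
print("The cluster fractions quantify how many CD8 T cells sit in direct "
      "contact range of tumour cells or APCs in the tissue section.")
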