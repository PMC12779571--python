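"""Antigen-specific T cells outcompete bystanders for tumour-cell conjugates.

Simulates a flow-cytometry competition co-culture (a 40:60 mix of
antigen-specific and non-specific T cells with tumour cells), gates the
double-positive heterotypic clusters, and estimates the cluster-over-singlet
fold enrichment of specific T cells with a bootstrap confidence interval.
Also reports how many clustered events a standard scatter area-vs-height
singlet gate throws away.
"""

import heteroclust as hc
from heteroclust.cytocompete import fold_enrichment, singlet_gate_loss

THRESHOLDS = {"t_label": 100.0, "tumour_label": 100.0, "specific_marker": 100.0}

events, truth = hc.gen_competition_events(
    n_tumour=50_000, n_t=50_000,
    input_specific_fraction=0.40,      # 40:60 specific:non-specific input mix
    planted_fold_change=2.7,
    cluster_fraction=0.20,
    seed=1,
)
est = fold_enrichment(events, THRESHOLDS, n_boot=1000, seed=1)

print(f"input specific fraction : {truth.input_specific_fraction:.3f}")
print(f"specific among singlets : {est.singlet_fraction:.3f}")
print(f"specific among clusters : {est.cluster_fraction:.3f}")
print(f"fold enrichment         : {est.fold_change:.2f} "
      f"(95% CI {est.ci_low:.2f}-{est.ci_high:.2f})")
if truth.clamped:
    print("note: at a 40% input the clustered specificity probability "
          "saturates at 1, capping the observable fold change at 1/0.40 = 2.5")

loss = singlet_gate_loss(events)
print(f"clustered events lost to the singlet gate: "
      f"{100 * loss['T-tumour cluster']:.0f}%")
print("A fold change above 1 means specific T cells are over-represented in "
      "heterotypic clusters; the gate loss shows such clusters are discarded "
      "by standard single-cell gating.")
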