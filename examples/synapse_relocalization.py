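"""Immune-synapse marker relocalization in imaging-flow doublets.

Generates touching T cell / tumour cell doublet images whose synapse-marker
channel places half of its membrane mass on the contact arc, then runs the
full measurement pipeline: variance-filtered bright-field + normalized marker
channels as segmentation input, watershed segmentation with 2-px label
contraction, k-means cell typing, 1:1 doublet extraction, and interface vs
non-interface membrane means with a paired Wilcoxon test.
"""

import heteroclust as hc

images, truth = hc.gen_synapse_images(
    n_doublets=50, n_singlets=5, relocalization_strength=0.5, seed=1)
res = hc.analyze_synapse_cohort(images)

print(f"doublets scored                 : {res['n_scored']}")
print(f"interface membrane mean         : {res['mean_interface']:.1f}")
print(f"non-interface membrane mean     : {res['mean_noninterface']:.1f}")
print(f"interface / non-interface ratio : {res['mean_ratio']:.2f}")
print(f"recovered relocalized fraction  : {res['mean_relocalized_fraction']:.2f} "
      f"(planted {truth.relocalization_strength})")
print(f"paired Wilcoxon p               : {res['p']:.2e}")
print("A ratio above 1 (and a small p) indicates the marker concentrates on "
      "the T cell-tumour cell contact, the signature of an immunological "
      "synapse; the recovered fraction estimates how much of the membrane "
      "signal has relocalized.")
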