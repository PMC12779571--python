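"""Cluster-vs-singlet cell-state enrichment with a patient random effect.

Generates a multi-patient CD8 single-cell dataset in which exhausted states
are enriched among cluster-derived cells (planted log-odds +1.0 for Tex),
then computes equal-patient-weighted state frequencies and fits the binomial
random-intercept model (interaction status fixed effect, patient random
intercept), with the stratified permutation test as an independent check.
Also demonstrates hashtag demultiplexing and neighbour-smoothed CD39 calls.
"""

import heteroclust as hc
from heteroclust.scquant import (
    cd39_status,
    hashtag_demux,
    state_enrichment_test,
    state_frequencies_equalweight,
)

ds, tcr = hc.gen_sc_dataset(n_patients=4, cells_per_patient=2000,
                            n_genes=300, seed=1)

freqs = state_frequencies_equalweight(ds)
print("equal-patient-weighted state frequencies (%):")
print((100 * freqs).round(1).to_string())

res = state_enrichment_test(ds, states=["Tex", "Tex_Tprol", "Tn", "Tem"],
                            with_permutation=True, n_perm=1000)
print("\ncluster-vs-singlet enrichment (binomial GLMM):")
print(res[["state", "log_odds", "se", "p_adj", "p_perm"]].round(4).to_string(index=False))

hashes = ds.obs[["hash1_count", "hash2_count"]].rename(
    columns={"hash1_count": "hash1", "hash2_count": "hash2"})
call = hashtag_demux(hashes)
print("\nhashtag demultiplexing:", call.value_counts().to_dict())

status = cd39_status(ds)
rescued = (status[ds.obs.truth_cd39_dropout] == "CD39+").mean()
print(f"CD39 dropout rescue via 10-nearest-neighbour smoothing: {100 * rescued:.0f}%")
print("\nPositive log-odds with small adjusted p mean the state is "
      "over-represented among cluster-derived T cells after accounting for "
      "patient-to-patient abundance differences.")
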