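"""Single-cell QC, demultiplexing, frequencies, enrichment, CD39 calls and
clonotype analytics."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import heteroclust as hc
from heteroclust.scquant import (
    cd39_status,
    clonotype_build,
    clonotype_compare,
    hashtag_demux,
    qc_filter,
    state_enrichment_test,
    state_frequencies_equalweight,
)


def _adata(counts, mito_flags, **obs):
    counts = np.asarray(counts)
    n = counts.shape[0]
    obs = pd.DataFrame(obs, index=[f"c{i}" for i in range(n)]) if obs else pd.DataFrame(
        index=[f"c{i}" for i in range(n)])
    var = pd.DataFrame({"mito": mito_flags},
                       index=[f"g{j}" for j in range(counts.shape[1])])
    return ad.AnnData(X=sparse.csr_matrix(np.asarray(counts)), obs=obs, var=var)


class TestQC:
    def test_hand_built_ten_cells(self):
        # 5 genes, gene 4 mitochondrial; detected-gene thresholds scaled down
        rows = [
            [1, 1, 1, 0, 0],   # 3 detected, 0% mito -> keep
            [1, 1, 0, 0, 0],   # 2 detected -> keep
            [1, 1, 1, 1, 1],   # 5 detected -> too many (max 4)
            [5, 5, 0, 0, 4],   # mito 4/14 = 28.6% -> removed
            [5, 5, 5, 0, 1],   # mito 1/16 = 6.2% -> keep
            [0, 0, 0, 0, 0],   # nothing detected -> too few
            [2, 2, 0, 0, 0],   # keep
            [9, 0, 9, 0, 0],   # keep
            [1, 1, 1, 1, 0],   # 4 detected -> keep
            [0, 0, 0, 0, 9],   # 100% mito -> removed (also 1 detected)
        ]
        ds = _adata(rows, [False] * 4 + [True])
        kept, report = qc_filter(ds, min_genes=2, max_genes=4, max_mito_pct=15)
        assert report["n_kept"] == 6
        assert kept.n_obs == 6

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, (80, 50))
        mito = [j < 5 for j in range(50)]
        ds = _adata(counts, mito)
        kept, _ = qc_filter(ds, min_genes=10, max_genes=30, max_mito_pct=20)
        expected = []
        for i in range(80):
            det = (counts[i] > 0).sum()
            tot = counts[i].sum()
            mito_pct = 100 * counts[i, :5].sum() / tot if tot else 0.0
            expected.append(10 <= det <= 30 and mito_pct <= 20)
        assert kept.n_obs == sum(expected)

    def test_default_thresholds_on_generated_cells(self):
        ds, _ = hc.gen_sc_dataset(2, 200, 2000, seed=9)
        kept, report = qc_filter(ds)
        assert report["n_kept"] > 0  # generated cells express a few hundred genes


class TestHashtagDemux:
    def test_accuracy_on_generated_bimodal_counts(self, sc_dataset):
        ds, _, _ = sc_dataset
        counts = ds.obs[["hash1_count", "hash2_count"]].rename(
            columns={"hash1_count": "hash1", "hash2_count": "hash2"})
        call = hashtag_demux(counts)
        truth = ds.obs.truth_hashtag
        pos = truth != "negative"
        assert (call[pos] == truth[pos]).mean() >= 0.98
        assert (call[~pos] == "negative").mean() >= 0.95

    def test_double_positive_removed(self):
        rng = np.random.default_rng(1)
        n = 500
        h1 = np.r_[rng.lognormal(np.log(300), 0.3, n // 2),
                   rng.lognormal(np.log(4), 0.5, n // 2)]
        h2 = np.r_[rng.lognormal(np.log(4), 0.5, n // 2),
                   rng.lognormal(np.log(300), 0.3, n // 2)]
        df = pd.DataFrame({"hash1": h1, "hash2": h2})
        df.loc[0, "hash2"] = 500.0  # above both thresholds
        call = hashtag_demux(df)
        assert call.iloc[0] == "doublet-removed"

    def test_degenerate_channel_fails_loudly(self):
        df = pd.DataFrame({"hash1": np.zeros(100), "hash2": np.ones(100)})
        with pytest.raises(ValueError):
            hashtag_demux(df)


class TestEqualWeightFrequencies:
    def _ds(self, rows):
        obs = pd.DataFrame(rows, columns=["patient", "origin", "state"])
        obs.index = [f"c{i}" for i in range(len(obs))]
        X = sparse.csr_matrix(np.ones((len(obs), 3)))
        var = pd.DataFrame({"mito": [False] * 3}, index=["g0", "g1", "g2"])
        return ad.AnnData(X=X, obs=obs, var=var)

    def test_single_patient_equals_raw_proportions(self):
        ds = self._ds([("P1", "o", "A")] * 3 + [("P1", "o", "B")])
        out = state_frequencies_equalweight(ds)
        assert out.loc["o", "A"] == pytest.approx(0.75)

    def test_two_patients_unweighted_mean(self):
        rows = [("P1", "o", "A")] * 2 + [("P1", "o", "B")] * 8   # 0.2
        rows += [("P2", "o", "A")] * 40 + [("P2", "o", "B")] * 60  # 0.4
        out = state_frequencies_equalweight(self._ds(rows))
        assert out.loc["o", "A"] == pytest.approx(0.3)

    def test_duplicating_a_patient_leaves_result_unchanged(self, sc_dataset):
        ds, _, _ = sc_dataset
        base = state_frequencies_equalweight(ds)
        p1 = ds[ds.obs.patient == "P1"]
        dup = ad.concat([ds, p1], index_unique="-")
        out = state_frequencies_equalweight(dup)
        pd.testing.assert_frame_equal(base, out, check_like=True)

    def test_rows_sum_to_one(self, sc_dataset):
        ds, _, _ = sc_dataset
        out = state_frequencies_equalweight(ds)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)


class TestEnrichment:
    def test_planted_log_odds_recovered(self, sc_dataset):
        ds, _, truth = sc_dataset
        res = state_enrichment_test(ds, states=["Tex"])
        assert res.log_odds.iloc[0] == pytest.approx(1.0, abs=0.35)
        assert res.p_adj.iloc[0] < 0.05

    def test_permutation_oracle_agrees(self, sc_dataset):
        ds, _, _ = sc_dataset
        res = state_enrichment_test(
            ds, states=["Tex", "Tn"], with_permutation=True, n_perm=500)
        for _, row in res.iterrows():
            assert (row.p < 0.05) == (row.p_perm < 0.05)

    def test_single_contrast_level_raises(self, sc_dataset):
        ds, _, _ = sc_dataset
        sub = ds[ds.obs.origin == "T-singlet"]
        with pytest.raises(ValueError):
            state_enrichment_test(sub, states=["Tex"])


class TestCD39:
    def test_dropout_rescue(self, sc_dataset):
        ds, _, _ = sc_dataset
        status = cd39_status(ds)
        dropped = ds.obs.truth_cd39_dropout
        assert (status[dropped] == "CD39+").mean() >= 0.90

    def test_all_zero_neighbourhood_is_negative(self):
        n = 30
        X = np.zeros((n, 2))
        obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
        var = pd.DataFrame({"mito": [False, False]}, index=["ENTPD1", "g1"])
        ds = ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var,
                        obsm={"X_embed": np.random.default_rng(0).normal(size=(n, 2))})
        assert (cd39_status(ds) == "CD39-").all()

    def test_k_too_large_raises(self, sc_dataset):
        ds, _, _ = sc_dataset
        with pytest.raises(ValueError):
            cd39_status(ds, k=ds.n_obs)


class TestClonotypes:
    def test_identical_pair_merges(self):
        tcr = pd.DataFrame({
            "cell_id": ["a", "a", "b", "b"],
            "chain": ["TRA", "TRB", "TRA", "TRB"],
            "cdr3_aa": ["CASSF", "CSARF", "CASSF", "CSARF"],
        })
        out = clonotype_build(tcr)
        assert out.clonotype.nunique() == 1
        assert (out.clonotype_size == 2).all()

    def test_missing_chain_excluded(self):
        tcr = pd.DataFrame({"cell_id": ["a"], "chain": ["TRB"], "cdr3_aa": ["CASSF"]})
        assert len(clonotype_build(tcr)) == 0

    def test_multichain_cell_is_distinct_clonotype(self):
        tcr = pd.DataFrame({
            "cell_id": ["a", "a", "a", "b", "b"],
            "chain": ["TRA", "TRA", "TRB", "TRA", "TRB"],
            "cdr3_aa": ["CAF", "CGF", "CTF", "CAF", "CTF"],
        })
        out = clonotype_build(tcr)
        assert out.loc["a", "clonotype"] != out.loc["b", "clonotype"]

    def test_malformed_cdr3_rejected_with_warning(self):
        tcr = pd.DataFrame({
            "cell_id": ["a", "a"], "chain": ["TRA", "TRB"],
            "cdr3_aa": ["CAS1F", "CSARF"],  # digit is invalid
        })
        with pytest.warns(UserWarning):
            out = clonotype_build(tcr)
        assert len(out) == 0  # alpha row rejected -> missing chain

    def test_brute_force_enumeration_agreement(self, sc_dataset):
        _, tcr, _ = sc_dataset
        cells = tcr.cell_id.unique()[:100]
        sub = tcr[tcr.cell_id.isin(cells)]
        out = clonotype_build(sub)
        # independent enumeration
        expected = {}
        for cid in cells:
            d = sub[sub.cell_id == cid]
            al = sorted(set(d[d.chain == "TRA"].cdr3_aa))
            be = sorted(set(d[d.chain == "TRB"].cdr3_aa))
            if al and be:
                expected[cid] = "+".join(al) + "|" + "+".join(be)
        assert dict(out.clonotype) == expected

    def test_small_clonotype_excluded_from_matched_comparison(self, sc_dataset):
        ds, tcr, _ = sc_dataset
        ct = clonotype_build(tcr)
        scores = pd.Series(np.random.default_rng(1).normal(size=ds.n_obs),
                           index=ds.obs_names)
        res = clonotype_compare(ct, ds, scores=scores, min_cells=10)
        if res["matched"] is not None:
            counts = (
                ds.obs.join(ct, how="inner")
                .query("origin in ('T-Tum cluster', 'T-APC cluster')")
                .pivot_table(index="clonotype", columns="origin",
                             values="patient", aggfunc="count", fill_value=0,
                             observed=True)
            )
            ok = counts.loc[res["matched"].index]
            assert (ok[["T-Tum cluster", "T-APC cluster"]] >= 10).all().all()
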