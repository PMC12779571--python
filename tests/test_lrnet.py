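"""Ligand-receptor curation rules, expression filtering and the
mean-plus-one-SD exclusivity assignment."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import heteroclust as hc
from heteroclust.lrnet import (
    activity_geneset,
    assign_subgroups,
    curate_pairs,
    expression_filter,
    merge_t_states,
)


def _row(w, ann, ppi, ct, sc, loc, i=0):
    return {
        "ligand": f"L{i}", "receptor": f"R{i}", "weight": w,
        "in_annotation_db": ann, "in_ppi": ppi,
        "in_celltalk_like": ct, "in_scsr_like": sc,
        "receptor_localization": loc,
    }


def _oracle(w, ann, ppi, ct, sc, loc):
    branch = ann or ppi or w > 0.9 or (w > 0.8 and (ct or sc))
    loc_ok = any(t in loc.lower() for t in ("cell membrane", "surface"))
    return w > 0.75 and branch and loc_ok


class TestCuration:
    def test_exhaustive_truth_table(self):
        rows = []
        expected = []
        i = 0
        for w in (0.7, 0.76, 0.81, 0.85, 0.91):
            for flags in itertools.product([False, True], repeat=4):
                for loc in ("Cell membrane", "Cell surface", "Nucleus"):
                    rows.append(_row(w, *flags, loc, i=i))
                    expected.append(_oracle(w, *flags, loc))
                    i += 1
        db = pd.DataFrame(rows)
        kept = curate_pairs(db)
        got = db.apply(lambda r: ((kept.ligand == r.ligand) &
                                  (kept.receptor == r.receptor)).any(), axis=1)
        np.testing.assert_array_equal(got.to_numpy(), np.asarray(expected))

    def test_planted_generator_rows(self, lr_table):
        kept = curate_pairs(lr_table)
        planted = lr_table[lr_table.planted]
        got = planted.apply(lambda r: ((kept.ligand == r.ligand) &
                                       (kept.receptor == r.receptor)).any(), axis=1)
        np.testing.assert_array_equal(got.to_numpy(),
                                      planted.truth_keep.astype(bool).to_numpy())

    def test_localization_substring_case_insensitive(self):
        db = pd.DataFrame([_row(0.95, 0, 0, 0, 0, "Single-pass CELL MEMBRANE protein")])
        assert len(curate_pairs(db)) == 1

    def test_missing_localization_dropped_with_warning(self):
        db = pd.DataFrame([_row(0.95, 1, 1, 1, 1, None)])
        with pytest.warns(UserWarning):
            assert len(curate_pairs(db)) == 0


class TestExpressionFilter:
    def _expr(self):
        # 20 cluster-origin cells; LIG expressed in 2 senders (10%),
        # REC in 7 receivers (35%)
        genes = ["LIGX", "RECX", "OTHER"]
        X = np.zeros((20, 3))
        X[:2, 0] = 5
        X[:7, 1] = 5
        X[:, 2] = 1
        obs = pd.DataFrame({"origin": ["T-Tum cluster"] * 20},
                           index=[f"c{i}" for i in range(20)])
        var = pd.DataFrame({"mito": [False] * 3}, index=genes)
        return ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)

    def test_hand_counted_percentages(self):
        expr = self._expr()
        db = pd.DataFrame([{"ligand": "LIGX", "receptor": "RECX"}])
        mask = np.ones(20, dtype=bool)
        out = expression_filter(db, expr, mask, mask, min_pct=0.10)
        assert out.pct_ligand_senders.iloc[0] == pytest.approx(0.10)
        assert out.pct_receptor_receivers.iloc[0] == pytest.approx(0.35)

    def test_below_threshold_dropped(self):
        expr = self._expr()
        db = pd.DataFrame([{"ligand": "LIGX", "receptor": "RECX"}])
        mask = np.ones(20, dtype=bool)
        out = expression_filter(db, expr, mask, mask, min_pct=0.11)
        assert len(out) == 0  # ligand at 10% < 11%

    def test_monotone_in_min_pct(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(30)]
        X = (rng.random((50, 30)) < rng.uniform(0.05, 0.5, 30)).astype(float)
        obs = pd.DataFrame({"origin": ["T-APC cluster"] * 50},
                           index=[f"c{i}" for i in range(50)])
        var = pd.DataFrame({"mito": [False] * 30}, index=genes)
        expr = ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)
        db = pd.DataFrame([{"ligand": genes[i], "receptor": genes[i + 15]}
                           for i in range(15)])
        mask = np.ones(50, dtype=bool)
        loose = expression_filter(db, expr, mask, mask, min_pct=0.10)
        strict = expression_filter(db, expr, mask, mask, min_pct=0.35)
        loose_pairs = set(zip(loose.ligand, loose.receptor))
        strict_pairs = set(zip(strict.ligand, strict.receptor))
        assert strict_pairs <= loose_pairs

    def test_no_overlapping_genes_raises(self):
        expr = self._expr()
        db = pd.DataFrame([{"ligand": "NOPE", "receptor": "NADA"}])
        mask = np.ones(20, dtype=bool)
        with pytest.raises(ValueError):
            expression_filter(db, expr, mask, mask)


class TestAssignment:
    def test_single_winner(self):
        assert assign_subgroups({"a": 10.0, "b": 1.0, "c": 1.0, "d": 1.0}) == "a"

    def test_two_above_threshold_is_unspecific(self):
        assert assign_subgroups({"a": 10.0, "b": 10.0, "c": 1.0, "d": 1.0}) == "unspecific"

    def test_equal_averages_unspecific(self):
        assert assign_subgroups({"a": 2.0, "b": 2.0, "c": 2.0}) == "unspecific"

    def test_hand_computed_threshold(self):
        # mean 3.25, population SD of (10,1,1,1) = 3.897 -> threshold 7.147
        vals = {"a": 10.0, "b": 1.0, "c": 1.0, "d": 1.0}
        s = np.array(list(vals.values()))
        thr = s.mean() + s.std()
        assert thr == pytest.approx(7.147, abs=1e-3)
        assert assign_subgroups(vals) == "a"
        # (8, 8, 1, 1): mean 4.5, SD 3.5, threshold 8.0 -> nothing strictly above
        assert assign_subgroups({"a": 8.0, "b": 8.0, "c": 1.0, "d": 1.0}) == "unspecific"

    def test_order_and_scale_invariance(self):
        v = {"a": 5.0, "b": 1.0, "c": 2.0}
        assert assign_subgroups(v) == assign_subgroups(dict(reversed(v.items())))
        assert assign_subgroups({k: 100 * x for k, x in v.items()}) == assign_subgroups(v)

    def test_single_subgroup_unspecific(self):
        with pytest.warns(UserWarning):
            assert assign_subgroups({"only": 5.0}) == "unspecific"


class TestHelpers:
    def test_t_state_merging(self):
        s = pd.Series(["TOXhigh_Tex", "MKI67high_Tex_Tprol", "Tn", "ISG"])
        assert merge_t_states(s).tolist() == ["Tex", "Tprol", "Tn_Tmem", "ISG"]

    def test_activity_geneset_filter(self):
        de = pd.DataFrame({
            "gene": ["a", "b", "c", "d"],
            "avg_log2FC": [0.5, 0.05, 0.5, 0.5],
            "p_adj": [0.01, 0.01, 0.2, 0.01],
            "pct_group1": [0.5, 0.5, 0.5, 0.01],
        })
        assert activity_geneset(de) == ["a"]


class TestPropertyBased:
    from hypothesis import given, settings, strategies as st

    @given(
        w=st.floats(0.0, 1.0),
        ann=st.booleans(), ppi=st.booleans(), ct=st.booleans(), sc=st.booleans(),
        loc=st.sampled_from(["Cell membrane", "Cell surface", "Cytoplasm",
                             "Nucleus", "Secreted", "cell MEMBRANE; Cytoplasm"]),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_curation_matches_oracle_on_arbitrary_rows(self, w, ann, ppi, ct, sc, loc):
        db = pd.DataFrame([_row(w, ann, ppi, ct, sc, loc)])
        assert (len(curate_pairs(db)) == 1) == _oracle(w, ann, ppi, ct, sc, loc)

    @given(vals=st.lists(st.floats(0.0, 100.0), min_size=2, max_size=8))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_assignment_always_one_winner_or_unspecific(self, vals):
        means = {f"g{i}": v for i, v in enumerate(vals)}
        out = assign_subgroups(means)
        s = np.array(vals)
        above = (s > s.mean() + s.std()).sum()
        assert (out == "unspecific") == (above != 1)
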