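"""Marker statistics, BH correction and pseudobulk NB differential expression."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats as st
from hypothesis import given, settings, strategies as hst

import metaniche as mn
from conftest import brute_force_bh, exact_ranksum_p
from metaniche.core import NormalizedMatrix
from metaniche.rank_stats import _size_factors


def _norm_from(values, symbols=None):
    values = np.asarray(values, dtype=float)
    g = symbols or [f"g{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(values, pd.Index(g), np.array(g),
                            pd.Index([f"c{i}" for i in range(values.shape[1])]),
                            scale=1e4, log=True)


class TestBenjaminiHochberg:
    def test_hand_step_up(self):
        np.testing.assert_allclose(mn.benjamini_hochberg([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert mn.benjamini_hochberg([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(mn.benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mn.benjamini_hochberg([0.5, 1.5])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(hst.integers(1, 50), hst.integers(0, 10_000))
    def test_matches_brute_force_and_statsmodels(self, n, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(n)
        mine = mn.benjamini_hochberg(p)
        np.testing.assert_allclose(mine, brute_force_bh(p), atol=1e-12)
        from statsmodels.stats.multitest import multipletests
        np.testing.assert_allclose(
            mine, multipletests(p, method="fdr_bh")[1], atol=1e-12)


class TestWilcoxonMarkers:
    def test_constant_gene_flagged(self):
        vals = np.vstack([np.ones(8), np.arange(8.0)])
        norm = _norm_from(vals)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        res = mn.wilcoxon_markers(norm, labels, "a")
        row = res.set_index("gene_id").loc["g0"]
        assert row["z"] == 0 and row["p"] == 1 and row["constant"]

    def test_exact_small_group_example(self):
        # in-cluster {4,5,6} vs out {1,2,3}: exact two-sided p = 0.1, Z > 0
        vals = np.array([[4.0, 5.0, 6.0, 1.0, 2.0, 3.0]])
        norm = _norm_from(vals)
        labels = np.array(["in"] * 3 + ["out"] * 3)
        res = mn.wilcoxon_markers(norm, labels, "in")
        assert res["p"].iloc[0] == pytest.approx(0.1)
        assert res["p"].iloc[0] == pytest.approx(exact_ranksum_p(vals[0, :3], vals[0, 3:]))
        assert res["z"].iloc[0] > 0

    def test_z_p_consistency(self, filtered_cohort):
        _, fcells, _, _, norm = filtered_cohort
        res = mn.wilcoxon_markers(norm, fcells["cell_type"].to_numpy(), "tumor")
        ok = res["p"] > 1e-300
        z_from_p = st.norm.isf(res.loc[ok, "p"] / 2)
        np.testing.assert_allclose(np.abs(res.loc[ok, "z"]), z_from_p, rtol=1e-6)

    def test_planted_markers_exceed_cutoff(self, filtered_cohort):
        _, fcells, _, truth, norm = filtered_cohort
        res = mn.wilcoxon_markers(norm, fcells["cell_type"].to_numpy(), "T").set_index("gene_id")
        t_markers = truth.genes.loc[truth.genes["marker_of"] == "T", "gene_id"]
        assert (res.loc[t_markers, "z"] > 3).all()

    def test_asymptotic_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        vals = rng.poisson(2, size=(50, 120)).astype(float)
        labels = np.array(["a"] * 40 + ["b"] * 80)
        norm = _norm_from(vals)
        res = mn.wilcoxon_markers(norm, labels, "a")
        ref = st.mannwhitneyu(vals[:, :40], vals[:, 40:], axis=1,
                              alternative="two-sided", method="asymptotic")
        np.testing.assert_allclose(res["p"], ref.pvalue, rtol=1e-8)


class TestMakePseudobulk:
    def _toy(self):
        counts = sp.csr_matrix(np.array([[1, 3, 5], [2, 4, 6]]))
        cells = pd.DataFrame({
            "cell_id": ["c1", "c2", "c3"],
            "sample_id": ["s1", "s1", "s2"],
            "condition": "metastatic",
            "cell_type": ["T", "T", "T"],
        })
        return counts, cells

    def test_summation(self):
        counts, cells = self._toy()
        pb, _ = mn.make_pseudobulk(counts, cells, "T", min_cells=1)
        np.testing.assert_array_equal(pb["s1"], [4, 6])
        np.testing.assert_array_equal(pb["s2"], [5, 6])

    def test_min_cells_excludes_sample(self):
        counts, cells = self._toy()
        pb, audit = mn.make_pseudobulk(counts, cells, "T", min_cells=2)
        assert list(pb.columns) == ["s1"]
        assert not audit.set_index("sample_id").loc["s2", "included"]

    def test_nine_cells_excluded_ten_included(self):
        counts = sp.csr_matrix(np.ones((2, 19), dtype=int))
        cells = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(19)],
            "sample_id": ["s1"] * 9 + ["s2"] * 10,
            "condition": "metastatic",
            "cell_type": "T",
        })
        pb, _ = mn.make_pseudobulk(counts, cells, "T", min_cells=10)
        assert list(pb.columns) == ["s2"]

    def test_cell_order_invariance(self):
        counts, cells = self._toy()
        pb1, _ = mn.make_pseudobulk(counts, cells, "T", min_cells=1)
        perm = [2, 0, 1]
        pb2, _ = mn.make_pseudobulk(counts[:, perm],
                                    cells.iloc[perm].reset_index(drop=True),
                                    "T", min_cells=1)
        pd.testing.assert_frame_equal(pb1, pb2)

    def test_all_excluded_raises(self):
        counts, cells = self._toy()
        with pytest.raises(ValueError, match="no sample"):
            mn.make_pseudobulk(counts, cells, "T", min_cells=100)


class TestPseudobulkDE:
    def _simulate(self, seed, n_genes=800, fold=4.0, n_planted=40, n=5):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(4, 1, n_genes)
        alpha = 0.01
        planted = rng.choice(n_genes, n_planted, replace=False)
        def draw(m, k):
            return rng.poisson(rng.gamma(1 / alpha, alpha * m[:, None] * np.ones((1, k))))
        mu_a = mu.copy()
        mu_a[planted] *= fold
        idx = pd.Index([f"g{i}" for i in range(n_genes)])
        a = pd.DataFrame(draw(mu_a, n), index=idx)
        b = pd.DataFrame(draw(mu, n), index=idx)
        return a, b, planted

    def test_identical_groups_give_zero_fold(self):
        a, _, _ = self._simulate(0, fold=1.0, n_planted=0)
        res = mn.pseudobulk_de(a, a.copy())
        assert np.nanmax(np.abs(res["log2_fc"])) < 1e-6

    def test_planted_recovery_and_error_control(self):
        a, b, planted = self._simulate(1)
        res = mn.pseudobulk_de(a, b).set_index("gene_id")
        names = [f"g{i}" for i in planted]
        sens = (res.loc[names, "p_adj"] < 0.05).mean()
        nulls = res.drop(index=names)
        fpr = (nulls["p_adj"] < 0.05).mean()
        assert sens >= 0.8 and fpr <= 0.05
        # planted genes are upregulated in group A: positive log2 fold change
        assert res.loc[names, "log2_fc"].median() == pytest.approx(2.0, abs=0.3)

    def test_size_factors_proportional_to_scalars(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(60, size=(200, 1)).astype(float) + 1
        scalars = np.array([1.0, 2.0, 0.5, 4.0])
        sf = _size_factors(base * scalars)
        ratio = sf / scalars
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)

    def test_zero_genes_reported_untested(self):
        a, b, _ = self._simulate(3, n_genes=50, n_planted=0)
        a.iloc[7] = 0
        b.iloc[7] = 0
        res = mn.pseudobulk_de(a, b).set_index("gene_id")
        assert not res.loc["g7", "tested"]
        assert res["tested"].sum() == 49

    def test_direction_agrees_with_deseq2(self):
        """Independent cross-check: strong planted effects point the same way."""
        a, b, planted = self._simulate(4, n_genes=300, n_planted=20)
        res = mn.pseudobulk_de(a, b).set_index("gene_id")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats
        counts = pd.concat([a, b], axis=1).T.reset_index(drop=True)
        counts.columns = [f"g{i}" for i in range(300)]
        meta = pd.DataFrame({"condition": ["A"] * 5 + ["B"] * 5})
        dds = DeseqDataSet(counts=counts, metadata=meta, design="~condition",
                           quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "A", "B"], quiet=True)
        ds.summary()
        ref = ds.results_df
        names = [f"g{i}" for i in planted]
        assert (np.sign(ref.loc[names, "log2FoldChange"])
                == np.sign(res.loc[names, "log2_fc"])).all()
        both = ref.index
        r = np.corrcoef(ref.loc[both, "log2FoldChange"],
                        res.loc[both, "log2_fc"])[0, 1]
        assert r > 0.95
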