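"""Normalisation, DE stand-in, signature selection and hierarchical clustering."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import discquant as dq
from discquant.clustering import (
    center_rows,
    co_cluster_purity,
    hcluster_genes,
    hcluster_samples,
    select_signature,
    simple_de,
    size_factors,
    vst,
)
from discquant.synthetic import CountSimParams, simulate_expression


class TestSizeFactors:
    def test_doubled_sample(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        f = size_factors(counts)
        assert f["s1"] == pytest.approx(1 / np.sqrt(2))
        assert f["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_samples(self):
        counts = pd.DataFrame({"a": [5, 7], "b": [5, 7], "c": [5, 7]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_three_scaled_samples(self):
        base = np.array([10, 25, 40, 100])
        counts = pd.DataFrame({"a": base, "b": 2 * base, "c": 4 * base})
        f = size_factors(counts).to_numpy()
        assert np.allclose(f / f[0], [1, 2, 4])
        assert np.prod(f) == pytest.approx(1.0)  # geometric mean 1

    def test_no_common_gene_raises(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)


class TestVst:
    def test_values(self):
        counts = pd.DataFrame({"s": [0, 7]})
        f = pd.Series({"s": 1.0})
        out = vst(counts, f)
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[1, 0] == pytest.approx(3.0)  # log2(8)

    def test_joint_scaling_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, (20, 4)), columns=list("abcd"))
        f = pd.Series(1.0, index=counts.columns)
        assert np.allclose(vst(counts, f), vst(2 * counts, 2 * f))

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            vst(pd.DataFrame({"a": [1]}), pd.Series({"a": 0.0}))


class TestSimpleDe:
    def test_identical_groups_zero_lfc(self):
        rng = np.random.default_rng(0)
        block = rng.poisson(40, (100, 3))
        counts = pd.DataFrame(
            np.hstack([block, block]),
            columns=[f"r{i}" for i in range(3)] + [f"t{i}" for i in range(3)],
        )
        groups = {f"r{i}": "ref" for i in range(3)} | {f"t{i}": "trt" for i in range(3)}
        de = simple_de(counts, groups, "ref", "trt")
        assert (de.table["log2fc"] == 0.0).all()
        assert not de.table["significant"].any()

    def test_null_design_false_positives_rare(self):
        # BH at alpha 0.01 on 2000 independent null genes: a handful at most
        calls = []
        for seed in range(3):
            p = CountSimParams(log2fc_embryonic=0.0, log2fc_neural=0.0)
            counts, meta = simulate_expression(p, seed)
            de = simple_de(counts, meta["group"], "control", "tumor")
            calls.append(len(de.significant_genes))
        assert max(calls) <= 5

    def test_power_on_strong_effects(self):
        # |log2FC| = 3, n = 4 vs 4, dispersion 0.1: nearly always detected
        p = CountSimParams(
            n_genes=200,
            embryonic_module_size=50,
            neural_module_size=0,
            groups=(("control", 4), ("tumor", 4)),
            log2fc_embryonic=3.0,
            log2fc_neural=0.0,
            dispersion=0.1,
        )
        rates = []
        for seed in range(3):
            counts, meta = simulate_expression(p, seed)
            de = simple_de(counts, meta["group"], "control", "tumor")
            emb = [g for g in counts.index if g.startswith("emb")]
            rates.append(de.table.loc[emb, "significant"].mean())
        assert np.mean(rates) >= 0.9

    def test_bh_monotone_and_bounded(self):
        counts, meta = simulate_expression(CountSimParams(), 11)
        de = simple_de(counts, meta["group"], "control", "tumor")
        t = de.table.sort_values("pvalue")
        assert (t["padj"] >= t["pvalue"] - 1e-12).all()
        assert t["padj"].between(0, 1).all()
        assert (np.diff(t["padj"]) >= -1e-12).all()
        # independent BH oracle
        from scipy.stats import false_discovery_control

        assert np.allclose(
            de.table["padj"], false_discovery_control(de.table["pvalue"], method="bh")
        )

    def test_small_group_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [2, 3], "c": [3, 4]})
        groups = {"a": "x", "b": "y", "c": "y"}
        with pytest.raises(ValueError):
            simple_de(counts, groups, "x", "y")


class TestSignature:
    def _de(self, seed=0):
        counts, meta = simulate_expression(CountSimParams(), seed)
        return counts, simple_de(counts, meta["group"], "control", "tumor")

    def test_disjoint_annotation_raises(self):
        _, de = self._de()
        with pytest.raises(ValueError):
            select_signature(de, {"not_a_gene"})

    def test_superset_annotation_returns_de_set(self):
        counts, de = self._de()
        sig = select_signature(de, set(counts.index))
        assert sorted(sig.genes) == sorted(de.significant_genes)

    def test_module_design_recovers_both_modules(self):
        counts, de = self._de(seed=4)
        tf = {g for g in counts.index if g.startswith(("emb", "neu"))}
        sig = select_signature(de, tf)
        # essentially the 124 module genes, none of the background
        assert len(sig.genes) >= 0.9 * 124
        assert all(g.startswith(("emb", "neu")) for g in sig.genes)


class TestCenterRows:
    def test_examples(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        out = center_rows(m)
        assert np.allclose(out.iloc[0], [-1, 0, 1])
        assert np.allclose(out.iloc[1], 0.0)

    @given(
        st.lists(
            st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=6),
            min_size=1,
            max_size=5,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_idempotent(self, rows):
        m = pd.DataFrame(rows)
        once = center_rows(m)
        twice = center_rows(once)
        assert np.allclose(once, twice, atol=1e-6)


class TestHierarchicalClustering:
    def test_duplicated_sample_merges_first_at_zero(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        m["dup"] = m["a"]
        dend = hcluster_samples(m)
        assert dend.heights[0] == pytest.approx(0.0, abs=1e-12)
        merged = set(dend.linkage_matrix[0, :2].astype(int))
        assert merged == {list(m.columns).index("a"), list(m.columns).index("dup")}

    def test_affine_copy_has_zero_distance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=40)
        m = pd.DataFrame({"a": a, "b": 2 * a + 5, "c": rng.normal(size=40)})
        dend = hcluster_samples(m)
        assert dend.heights[0] == pytest.approx(0.0, abs=1e-9)

    def test_anticorrelated_distance_two(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        m = pd.DataFrame({"a": a, "b": -a})
        dend = hcluster_samples(m)
        assert dend.heights[-1] == pytest.approx(2.0)

    def test_zero_variance_sample_named_in_error(self):
        m = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(ValueError, match="flat"):
            hcluster_samples(m)

    def test_gene_examples(self):
        m = pd.DataFrame([[0.0, 0.0], [3.0, 4.0], [3.0, 4.0]], index=["g1", "g2", "g3"])
        dend = hcluster_genes(m)
        assert dend.heights[0] == pytest.approx(0.0)  # identical rows merge at 0
        assert dend.heights[-1] == pytest.approx(5.0)  # 3-4-5 triangle

    def test_gene_distances_match_brute_force(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(6, 5)), index=[f"g{i}" for i in range(6)])
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(m.to_numpy()))
        brute = np.array(
            [
                [np.sqrt(((m.iloc[i] - m.iloc[j]) ** 2).sum()) for j in range(6)]
                for i in range(6)
            ]
        )
        assert np.allclose(d, brute)
        # linkage heights are bounded by pairwise distances and monotone
        dend = hcluster_genes(m)
        assert (np.diff(dend.heights) >= -1e-12).all()

    def test_gene_clustering_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(8, 6)))
        perm = rng.permutation(6)
        d1 = hcluster_genes(m)
        d2 = hcluster_genes(m.iloc[:, perm])
        assert np.allclose(d1.linkage_matrix, d2.linkage_matrix)

    def test_newick_round_trip(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        nwk = hcluster_samples(m).to_newick()
        import skbio

        tree = skbio.TreeNode.read([nwk])
        assert sorted(t.name for t in tree.tips()) == list("abcde")


class TestCoClusterPurity:
    def _dend_from(self, m):
        return hcluster_samples(pd.DataFrame(m))

    def test_trivial_cases(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        disc_base = rng.normal(size=30)
        m = pd.DataFrame(
            np.column_stack(
                [
                    base,
                    base + rng.normal(0, 0.01, 30),
                    disc_base + rng.normal(0, 0.01, 30),
                    disc_base + rng.normal(0, 0.01, 30),
                ]
            ),
            columns=["tum1", "emb1", "disc1", "disc2"],
        )
        groups = {"tum1": "tumor", "emb1": "embryo", "disc1": "disc", "disc2": "disc"}
        dend = hcluster_samples(m)
        assert co_cluster_purity(dend, groups, 2, "tumor", "embryo") == 1.0
        assert co_cluster_purity(dend, groups, 2, "disc", "embryo") == 0.0

    def test_k_bounds(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        dend = hcluster_samples(m)
        with pytest.raises(ValueError):
            co_cluster_purity(dend, {"a": "x", "b": "x", "c": "y"}, 7, "x", "y")
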