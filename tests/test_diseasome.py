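"""Pairwise matrices, complete-linkage clustering, the percentile edge
rule, cross-collection comparisons, and exports."""

import numpy as np
import pytest

import networkx as nx

from netsep import (
    MappedModule,
    SeparationConfig,
    build_shdn,
    cluster_diseases,
    cross_collection_separation,
    export_diseasome,
    pairwise_separation_matrix,
)
from netsep.diseasome import PairwiseMatrix, negative_percentile_threshold


def matrix_from_s(labels, s, s_tilde=None, p=None):
    s = np.asarray(s, dtype=float)
    n = len(labels)
    if s_tilde is None:
        s_tilde = np.tanh(-s) * 0.49  # any monotone stand-in
        np.fill_diagonal(s_tilde, 0.0)
    if p is None:
        p = np.full((n, n), 0.01)
        np.fill_diagonal(p, 1.0)
    return PairwiseMatrix(labels=tuple(labels), s=s, p=np.asarray(p), s_tilde=np.asarray(s_tilde))


class TestPairwiseMatrix:
    def test_two_modules_one_pair(self, small_ba):
        nodes = sorted(small_ba.nodes())
        mods = [
            MappedModule("a", frozenset(nodes[:8])),
            MappedModule("b", frozenset(nodes[50:58])),
        ]
        cfg = SeparationConfig(replicates=100, seed=1, min_occupancy=20)
        m = pairwise_separation_matrix(small_ba, mods, cfg=cfg)
        assert m.labels == ("a", "b")
        assert m.s.shape == (2, 2)
        assert m.s[0, 1] == m.s[1, 0]
        assert len(m.results) == 1

    def test_identical_member_sets_give_zero_separation(self, small_ba):
        nodes = sorted(small_ba.nodes())
        members = frozenset(nodes[20:30])
        mods = [MappedModule("x", members), MappedModule("y", members)]
        cfg = SeparationConfig(replicates=100, seed=2, min_occupancy=20)
        m = pairwise_separation_matrix(small_ba, mods, cfg=cfg)
        assert m.s[0, 1] == 0.0

    def test_input_order_invariance(self, small_ba):
        nodes = sorted(small_ba.nodes())
        mods = [
            MappedModule("a", frozenset(nodes[:8])),
            MappedModule("b", frozenset(nodes[50:58])),
            MappedModule("c", frozenset(nodes[100:108])),
        ]
        cfg = SeparationConfig(replicates=60, seed=5, min_occupancy=20)
        m1 = pairwise_separation_matrix(small_ba, mods, cfg=cfg)
        m2 = pairwise_separation_matrix(small_ba, mods[::-1], cfg=cfg)
        assert m1.labels == m2.labels
        assert np.array_equal(m1.s, m2.s)


class TestClustering:
    def test_unique_minimum_merges_first(self):
        s = np.array([[0, -1, 2], [-1, 0, 2], [2, 2, 0]], dtype=float)
        c = cluster_diseases(matrix_from_s(["A", "B", "C"], s))
        first = c.merges[0]
        assert first[0] | first[1] == {"A", "B"}

    def test_all_equal_ties_resolved_lexicographically(self):
        s = np.full((3, 3), 1.0)
        np.fill_diagonal(s, 0.0)
        c = cluster_diseases(matrix_from_s(["A", "B", "C"], s))
        first = c.merges[0]
        assert first[0] | first[1] == {"A", "B"}
        assert c.leaf_order[0] == "C" or c.leaf_order == ("C", "A", "B") or c.leaf_order == ("A", "B", "C")

    def test_heights_nondecreasing_and_count(self):
        rng = np.random.default_rng(0)
        n = 7
        s = rng.normal(size=(n, n))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 0.0)
        c = cluster_diseases(matrix_from_s([f"d{i}" for i in range(n)], s))
        heights = [h for _, _, h in c.merges]
        assert len(heights) == n - 1
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_shift_invariance_of_merge_order(self):
        """Adding any constant to the separation matrix leaves the
        complete-linkage merge history unchanged."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            s = rng.normal(size=(n, n)) * rng.uniform(0.5, 3)
            s = (s + s.T) / 2
            np.fill_diagonal(s, 0.0)
            labels = [f"d{i}" for i in range(n)]
            base = cluster_diseases(matrix_from_s(labels, s))
            shift = float(rng.uniform(-5, 5))
            shifted = s + shift
            np.fill_diagonal(shifted, 0.0)
            other = cluster_diseases(matrix_from_s(labels, shifted))
            assert [frozenset(a | b) for a, b, _ in base.merges] == [
                frozenset(a | b) for a, b, _ in other.merges
            ]

    def test_leaf_order_smaller_cluster_first(self):
        # AB merge low, C joins later: singleton C leads the final order
        s = np.array([[0, -1, 2], [-1, 0, 2], [2, 2, 0]], dtype=float)
        c = cluster_diseases(matrix_from_s(["A", "B", "C"], s))
        assert c.leaf_order == ("C", "A", "B")


class TestShdn:
    def test_percentile_interpolation(self):
        assert negative_percentile_threshold(
            np.array([-0.4, -0.3, -0.2, -0.1])
        ) == pytest.approx(-0.175)

    def test_admission_follows_percentile_rule(self):
        # disease D with negative s~ to E,F,G,H; intersection rule keeps
        # only edges admitted from D's side: -0.4, -0.3, -0.2
        labels = ["D", "E", "F", "G", "H"]
        st = np.zeros((5, 5))
        vals = {"E": -0.4, "F": -0.3, "G": -0.2, "H": -0.1}
        for j, l in enumerate(labels[1:], start=1):
            st[0, j] = st[j, 0] = vals[l]
        for i in range(1, 5):
            for j in range(i + 1, 5):
                st[i, j] = st[j, i] = 0.3  # partners mutually separated
        m = matrix_from_s(labels, np.zeros((5, 5)), s_tilde=st)
        d = build_shdn(m, edge_rule="intersection")
        assert d.thresholds["D"] == pytest.approx(-0.175)
        assert set(map(frozenset, d.graph.edges())) == {
            frozenset({"D", "E"}), frozenset({"D", "F"}), frozenset({"D", "G"})
        }

    def test_no_negative_values_isolated(self):
        st = np.array([[0, 0.2, 0.3], [0.2, 0, -0.1], [0.3, -0.1, 0]])
        m = matrix_from_s(["A", "B", "C"], np.zeros((3, 3)), s_tilde=st)
        d = build_shdn(m, edge_rule="union")
        assert d.graph.degree("A") == 0
        assert d.graph.has_edge("B", "C")  # each admits its only negative

    def test_union_admits_one_sided_edges(self):
        # B admits A (its only negative); A's threshold excludes B
        st = np.array([
            [0.0, -0.1, -0.6],
            [-0.1, 0.0, 0.4],
            [-0.6, 0.4, 0.0],
        ])
        m = matrix_from_s(["A", "B", "C"], np.zeros((3, 3)), s_tilde=st)
        union = build_shdn(m, edge_rule="union")
        inter = build_shdn(m, edge_rule="intersection")
        assert union.graph.has_edge("A", "B")
        assert not inter.graph.has_edge("A", "B")

    def test_metadata_on_nodes(self):
        st = np.array([[0, -0.2], [-0.2, 0]])
        m = matrix_from_s(["A", "B"], np.zeros((2, 2)), s_tilde=st)
        d = build_shdn(m, metadata={"A": {"module_size": 12}, "B": {"module_size": 7}})
        assert d.graph.nodes["A"]["module_size"] == 12


class TestCrossCollection:
    def test_pair_counting_and_stars(self, small_ba):
        nodes = sorted(small_ba.nodes())
        coll_a = [
            MappedModule("exprA", frozenset(nodes[:8])),
            MappedModule("exprB", frozenset(nodes[30:38])),
        ]
        coll_b = [
            MappedModule("curX", frozenset(nodes[60:68])),
            MappedModule("curY", frozenset(nodes[90:98])),
            MappedModule("curZ", frozenset(nodes[120:128])),
        ]
        cfg = SeparationConfig(replicates=60, seed=6, min_occupancy=20)
        df = cross_collection_separation(small_ba, coll_a, coll_b, cfg=cfg)
        assert (df["kind"] == "cross").sum() == 6
        assert (df["kind"] == "within_b").sum() == 3
        assert set(df["stars"]) <= {"", "*", "**", "***"}

    def test_module_against_itself_zero(self, small_ba):
        nodes = sorted(small_ba.nodes())
        members = frozenset(nodes[10:20])
        cfg = SeparationConfig(replicates=60, seed=6, min_occupancy=20)
        df = cross_collection_separation(
            small_ba,
            [MappedModule("same", members)],
            [MappedModule("same2", members)],
            cfg=cfg,
        )
        assert df.loc[df["kind"] == "cross", "s"].iloc[0] == 0.0


class TestExport:
    @pytest.fixture
    def small_outputs(self, small_ba, tmp_path):
        nodes = sorted(small_ba.nodes())
        mods = [
            MappedModule("a", frozenset(nodes[:8])),
            MappedModule("b", frozenset(nodes[50:58])),
            MappedModule("c", frozenset(nodes[100:108])),
        ]
        cfg = SeparationConfig(replicates=60, seed=3, min_occupancy=20)
        m = pairwise_separation_matrix(small_ba, mods, cfg=cfg)
        c = cluster_diseases(m)
        d = build_shdn(m, metadata={x.name: {"module_size": len(x.mapped)} for x in mods})
        return export_diseasome(d, c, m, tmp_path), d, c, m

    def test_graphml_round_trip(self, small_outputs):
        paths, d, _, m = small_outputs
        g2 = nx.read_graphml(paths["graphml"])
        assert set(g2.nodes()) == set(m.labels)
        assert {frozenset(e) for e in g2.edges()} == {
            frozenset(e) for e in d.graph.edges()
        }

    def test_newick_parses_with_all_leaves(self, small_outputs):
        import dendropy

        paths, _, c, m = small_outputs
        tree = dendropy.Tree.get(path=str(paths["newick"]), schema="newick")
        leaves = {l.taxon.label for l in tree.leaf_node_iter()}
        assert leaves == set(m.labels)

    def test_matrix_tsv_round_trip(self, small_outputs):
        import pandas as pd

        paths, _, _, m = small_outputs
        df = pd.read_csv(paths["s_matrix"], sep="\t", index_col=0)
        assert list(df.columns) == list(m.labels)
        assert np.allclose(df.values, m.s)

    def test_export_is_deterministic(self, small_ba, tmp_path):
        nodes = sorted(small_ba.nodes())
        mods = [
            MappedModule("a", frozenset(nodes[:8])),
            MappedModule("b", frozenset(nodes[50:58])),
        ]
        cfg = SeparationConfig(replicates=60, seed=3, min_occupancy=20)
        outs = []
        for sub in ("one", "two"):
            m = pairwise_separation_matrix(small_ba, mods, cfg=cfg)
            c = cluster_diseases(m)
            d = build_shdn(m)
            paths = export_diseasome(d, c, m, tmp_path / sub)
            outs.append(paths)
        for key in outs[0]:
            assert outs[0][key].read_bytes() == outs[1][key].read_bytes()
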