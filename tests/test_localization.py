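"""Localization metrics, degree binning, and the degree-matched null."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from netsep import (
    MappedModule,
    build_degree_bins,
    induced_module_metrics,
    localization_significance,
    sample_degree_matched,
)
from netsep._seeds import rng_for
from netsep.localization import _module_bin_counts

from oracles import enumerate_lcc_sizes


class TestInducedMetrics:
    @pytest.mark.parametrize(
        "members, expected",
        [
            ({"1", "2", "3"}, (2, 3, 2)),   # connected prefix of the path
            ({"1", "3", "5"}, (0, 1, 0)),   # independent set
        ],
    )
    def test_path_graph_modules(self, path5, members, expected):
        m = induced_module_metrics(path5, members)
        assert m.as_tuple() == expected

    def test_clique(self, triangle):
        assert induced_module_metrics(triangle, {"a", "b", "c"}).as_tuple() == (3, 3, 3)

    def test_tie_breaks_to_lexicographic_component(self):
        # equal-size components with different edge counts: the one
        # holding the lexicographically smallest member is reported
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])  # triangle, 3 edges
        g.add_edges_from([("x", "y"), ("y", "z")])              # path, 2 edges
        m = induced_module_metrics(g, {"a", "b", "c", "x", "y", "z"})
        assert m.total_edges == 5
        assert m.lcc_size == 3 and m.lcc_edges == 3  # triangle holds "a"

    def test_empty_module_rejected(self, path5):
        with pytest.raises(ValueError):
            induced_module_metrics(path5, set())


class TestDegreeBins:
    def test_regular_graph_single_bin(self, cycle6):
        bins = build_degree_bins(cycle6, min_occupancy=3)
        assert len(bins.bins) == 1
        assert set(bins.bins[0]) == set(cycle6.nodes())

    def test_star_hub_merged_when_alone(self):
        g = nx.star_graph(9)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        bins = build_degree_bins(g, min_occupancy=2)
        assert len(bins.bins) == 1  # lone hub absorbed into the leaf bin
        assert len(bins.bins[0]) == 10

    def test_min_occupancy_one_keeps_raw_bins(self):
        g = nx.star_graph(9)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        bins = build_degree_bins(g, min_occupancy=1)
        assert len(bins.bins) == 2  # [1,2) leaves and [8,16) hub

    def test_partition_property(self, small_ba):
        bins = build_degree_bins(small_ba, min_occupancy=20)
        all_nodes = [n for b in bins.bins for n in b]
        assert len(all_nodes) == small_ba.number_of_nodes()
        assert len(set(all_nodes)) == len(all_nodes)
        assert all(len(b) >= 20 for b in bins.bins)
        for (lo, hi), members in zip(bins.intervals, bins.bins):
            assert all(lo <= small_ba.degree(n) < hi for n in members)

    def test_occupancy_exceeding_nodes_rejected(self, cycle6):
        with pytest.raises(ValueError):
            build_degree_bins(cycle6, min_occupancy=7)


class TestDegreeMatchedSampling:
    def test_preserves_bin_histogram(self, small_ba):
        bins = build_degree_bins(small_ba, min_occupancy=20)
        rng = rng_for(3, "t")
        nodes = sorted(small_ba.nodes())
        module = set(nodes[::17][:12])
        want = _module_bin_counts(bins, small_ba, module)
        for _ in range(25):
            s = sample_degree_matched(small_ba, bins, module, rng)
            assert len(s) == len(module)
            got = _module_bin_counts(bins, small_ba, s)
            assert np.array_equal(got, want)

    def test_uniform_over_single_bin(self, cycle6):
        """On a regular graph every same-size subset is equally likely."""
        bins = build_degree_bins(cycle6, min_occupancy=6)
        rng = rng_for(11, "u")
        counts = {}
        draws = 3000
        for _ in range(draws):
            s = frozenset(sample_degree_matched(cycle6, bins, {"1", "2"}, rng))
            counts[s] = counts.get(s, 0) + 1
        assert len(counts) == 15
        p = 1 / 15
        se = math.sqrt(p * (1 - p) / draws)
        for c in counts.values():
            assert abs(c / draws - p) < 3 * se + 1e-9

    def test_forced_draw_full_module(self, cycle6):
        bins = build_degree_bins(cycle6, min_occupancy=6)
        rng = rng_for(0, "f")
        s = sample_degree_matched(cycle6, bins, set(cycle6.nodes()), rng)
        assert s == set(cycle6.nodes())

    def test_deterministic_under_seed(self, small_ba):
        bins = build_degree_bins(small_ba, min_occupancy=20)
        module = set(sorted(small_ba.nodes())[:10])
        a = sample_degree_matched(small_ba, bins, module, rng_for(5, "d"))
        b = sample_degree_matched(small_ba, bins, module, rng_for(5, "d"))
        assert a == b


class TestLocalizationSignificance:
    def test_default_replicates_is_thousand(self):
        import inspect

        sig = inspect.signature(localization_significance)
        assert sig.parameters["replicates"].default == 1000

    def test_cycle_pair_matches_exhaustive_null(self, cycle6):
        """Monte-Carlo null moments for lcc_size converge to the
        exhaustively enumerated values (adjacent pair on the 6-cycle)."""
        sizes = enumerate_lcc_sizes(cycle6, 2)
        exact_mean = float(np.mean(sizes))
        exact_sd = float(np.std(sizes))
        assert exact_mean == pytest.approx(1.4)
        assert exact_sd == pytest.approx(0.4899, abs=1e-4)

        m = MappedModule("adj", frozenset({"1", "2"}))
        R = 1000
        res = localization_significance(cycle6, m, replicates=R, seed=21, min_occupancy=6)
        sig = res["lcc_size"]
        se_mean = exact_sd / math.sqrt(R)
        se_sd = exact_sd / math.sqrt(2 * R)
        assert abs(sig.null_mean - exact_mean) < 3 * se_mean
        assert abs(sig.null_sd - exact_sd) < 3 * se_sd
        # observed lcc_size 2 against that null: z ~ 1.22, p ~ 0.11
        assert sig.observed == 2
        assert sig.z == pytest.approx(1.2247, abs=0.15)
        assert sig.p == pytest.approx(0.110, abs=0.03)

    def test_degenerate_null_flags(self, cycle6):
        # module = all nodes: every sample is the full set, sd = 0
        m = MappedModule("all", frozenset(cycle6.nodes()))
        res = localization_significance(cycle6, m, replicates=10, seed=0, min_occupancy=6)
        for k in ("total_edges", "lcc_size", "lcc_edges"):
            assert res[k].degenerate
            assert res[k].p == 1.0  # observed equals the null mean

    def test_p_is_upper_tail_of_z(self, small_ba):
        from scipy.stats import norm

        module = set(sorted(small_ba.nodes())[:8])
        res = localization_significance(
            small_ba, MappedModule("m", frozenset(module)), replicates=200,
            seed=9, min_occupancy=20,
        )
        for k, sig in res.metrics.items():
            if not sig.degenerate:
                assert sig.p == pytest.approx(float(norm.sf(sig.z)))
            assert 0.0 <= sig.empirical_p <= 1.0

    def test_too_few_replicates_rejected(self, cycle6):
        m = MappedModule("adj", frozenset({"1", "2"}))
        with pytest.raises(ValueError):
            localization_significance(cycle6, m, replicates=1, seed=0, min_occupancy=6)
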