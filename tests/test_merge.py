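"""Merge engine: collision null model, call graph, maximal cliques, and
clique-to-consensus merging."""

import itertools
import math
import random

import networkx as nx
import numpy as np
import pytest

from conftest import make_del, make_ins, random_call
from svclique.errors import ConfigError
from svclique.merge import (
    CallGraph,
    build_call_graph,
    calibrate_distance_threshold,
    collision_window,
    compatible,
    empirical_collision_probability,
    enumerate_maximal_cliques,
    merge_callsets,
    merge_cliques,
    pairwise_criteria,
    random_merge_probability,
)
from svclique.model import (
    DEFAULT_CRITERIA,
    MergeCriteria,
    MethodClass,
    SVCall,
    ToolProfile,
)
from svclique.vcf_io import CallSet


class TestRandomMergeProbability:
    @pytest.mark.parametrize(
        "k1,k2,window,expected",
        [(5, 7, 0, 0.0), (0, 100, 50, 0.0), (100, 0, 50, 0.0)],
    )
    def test_degenerate_zero(self, k1, k2, window, expected):
        assert random_merge_probability(k1, k2, 10**6, window) == expected

    def test_single_pair_is_window_over_genome(self):
        assert random_merge_probability(1, 1, 10**6, 50) == pytest.approx(50 / 10**6)

    def test_monotone_in_each_argument(self):
        base = random_merge_probability(100, 200, 10**6, 50)
        assert random_merge_probability(101, 200, 10**6, 50) >= base
        assert random_merge_probability(100, 201, 10**6, 50) >= base
        assert random_merge_probability(100, 200, 10**6, 51) >= base

    def test_exact_vs_approx_agree_in_small_probability_regime(self):
        """The exponential approximation tracks the exact form when both
        K1*K2*L/G and L/G are small."""
        configs = [
            (100, 200, 10**9, 50), (10, 10, 10**7, 100),
            (1000, 1000, 10**9, 100), (50, 40, 10**8, 25),
            (300, 300, 10**8, 80),
        ]
        for k1, k2, g, window in configs:
            assert k1 * k2 * window / g <= 0.1 and window / g <= 1e-4
            exact = random_merge_probability(k1, k2, g, window, "exact")
            approx = random_merge_probability(k1, k2, g, window, "approx")
            assert abs(exact - approx) < 1e-3

    def test_log_space_stability_for_huge_pair_counts(self):
        p = random_merge_probability(10**6, 10**6, 10**9, 100)
        assert p == 1.0  # astronomically many pairs: certainty, not NaN
        p2 = random_merge_probability(10**5, 1, 10**9, 1)
        assert 0.0 < p2 < 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            random_merge_probability(1, 1, 0, 0)
        with pytest.raises(ValueError):
            random_merge_probability(1, 1, 100, 101)
        with pytest.raises(ValueError):
            random_merge_probability(-1, 1, 100, 10)


class TestMonteCarloValidation:
    def test_closed_form_matches_placement_simulation(self, rng):
        """Uniformly placed call sets collide as often as the closed form
        predicts (criterion distance D maps to window 2D+1)."""
        k1, k2, g, d = 4, 6, 20_000, 50
        n = 20_000
        p_hat = empirical_collision_probability(k1, k2, g, d, n, rng)
        p = random_merge_probability(k1, k2, g, collision_window(d))
        se = math.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) <= 3 * se

    def test_engine_compatibility_frequency_matches_formula(self, rng):
        """The same comparison routed through compatible()/build_call_graph
        (length criterion disabled)."""
        k1, k2, g, d = 5, 5, 10_000, 40
        crit = MergeCriteria(d, 10**9)
        hits = 0
        n = 400
        for _ in range(n):
            a = [
                make_ins(f"a{i}", "t1", "chr1", int(rng.integers(1, g + 1)), 100)
                for i in range(k1)
            ]
            b = [
                make_ins(f"b{i}", "t2", "chr1", int(rng.integers(1, g + 1)), 100)
                for i in range(k2)
            ]
            graph = build_call_graph(
                [CallSet("t1", a), CallSet("t2", b)],
                global_criteria=crit,
                min_size=0,
                allow_same_tool=False,
            )
            if graph.n_edges > 0:
                hits += 1
        p = random_merge_probability(k1, k2, g, collision_window(d))
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) <= 3 * se


class TestCalibrate:
    def test_alpha_zero_gives_zero_window(self):
        assert calibrate_distance_threshold(10, 10, 10**6, 0.0) == 0

    @pytest.mark.parametrize("alpha", [0.0, 0.001, 0.01, 0.1, 0.5, 0.99])
    @pytest.mark.parametrize("k1,k2", [(1, 1), (2, 2), (3, 4)])
    def test_against_linear_scan_oracle(self, alpha, k1, k2):
        g = 5000
        scan = 0
        for window in range(g + 1):
            if random_merge_probability(k1, k2, g, window) <= alpha:
                scan = window
            else:
                break
        assert calibrate_distance_threshold(k1, k2, g, alpha) == scan

    def test_bracketing_and_monotonicity(self):
        g = 10**6
        prev = -1
        for alpha in (0.001, 0.01, 0.05, 0.2):
            window = calibrate_distance_threshold(20, 30, g, alpha)
            assert random_merge_probability(20, 30, g, window) <= alpha
            assert random_merge_probability(20, 30, g, window + 1) > alpha
            assert window >= prev
            prev = window

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            calibrate_distance_threshold(1, 1, 100, -0.1)
        with pytest.raises(ValueError):
            calibrate_distance_threshold(0, 5, 100, 0.1)


class TestCompatibility:
    def test_within_default_thresholds(self):
        a = make_del("a", "t1", "chr1", 971, 1030)   # center 1000, len 60
        b = make_del("b", "t2", "chr1", 1006, 1075)  # center 1040, len 70
        assert compatible(a, b, DEFAULT_CRITERIA)

    def test_breakpoint_distance_boundary(self):
        a = make_ins("a", "t1", "chr1", 1000, 50)
        assert compatible(a, make_ins("b", "t2", "chr1", 1050, 50), DEFAULT_CRITERIA)
        assert not compatible(a, make_ins("c", "t2", "chr1", 1051, 50), DEFAULT_CRITERIA)

    def test_type_and_chrom_mismatch(self):
        dele = make_del("a", "t1", "chr1", 991, 1010)
        ins = make_ins("b", "t2", "chr1", 1000, 20)
        assert not compatible(dele, ins, DEFAULT_CRITERIA)
        other = make_del("c", "t2", "chr2", 991, 1010)
        assert not compatible(dele, other, DEFAULT_CRITERIA)

    def test_unknown_length_is_vacuously_length_compatible(self):
        a = make_ins("a", "t1", "chr1", 1000, None)
        b = make_ins("b", "t2", "chr1", 1010, 5000)
        assert compatible(a, b, DEFAULT_CRITERIA)

    def test_pairwise_criteria_take_the_permissive_limit(self):
        sr = ToolProfile.for_method("sr", MethodClass.SPLIT_READ)
        iseg = ToolProfile.for_method("is", MethodClass.INTERNAL_SEGMENT)
        assert pairwise_criteria(sr, sr) == MergeCriteria(20, 10)
        assert pairwise_criteria(sr, iseg) == MergeCriteria(100, 100)
        assert pairwise_criteria(iseg, sr) == MergeCriteria(100, 100)


class TestCallGraph:
    def test_single_call(self):
        cs = CallSet("t", [make_ins("a", "t", "chr1", 100, 30)])
        graph = build_call_graph([cs], global_criteria=DEFAULT_CRITERIA)
        assert len(graph.order) == 1 and graph.n_edges == 0

    def test_path_graph_from_spaced_centers(self):
        calls = [
            make_ins("a", "t", "chr1", 100, 30),
            make_ins("b", "t", "chr1", 140, 30),
            make_ins("c", "t", "chr1", 180, 30),
        ]
        graph = build_call_graph(
            [CallSet("t", calls)], global_criteria=MergeCriteria(50, 20)
        )
        assert graph.adj["a"] == {"b"}
        assert graph.adj["b"] == {"a", "c"}

    def test_sliding_window_equals_all_pairs_oracle(self, rng):
        """The sweep construction reproduces the quadratic all-pairs edge
        set on 500 random calls with heterogeneous per-tool criteria."""
        profiles = {
            "sr": ToolProfile.for_method("sr", MethodClass.SPLIT_READ),
            "hy": ToolProfile.for_method("hy", MethodClass.HYBRID),
            "is": ToolProfile.for_method("is", MethodClass.INTERNAL_SEGMENT),
        }
        callsets = []
        for tool in profiles:
            calls = [
                random_call(rng, f"{tool}.{i}", tool, max_pos=20_000, max_len=150)
                for i in range(167)
            ]
            callsets.append(CallSet(tool, calls))
        graph = build_call_graph(callsets, profiles=profiles, min_size=0)

        expected = set()
        all_calls = list(graph.calls.values())
        for a, b in itertools.combinations(all_calls, 2):
            crit = pairwise_criteria(profiles[a.tool_id], profiles[b.tool_id])
            if compatible(a, b, crit):
                expected.add(frozenset((a.call_id, b.call_id)))
        got = {
            frozenset((u, v)) for u, nbrs in graph.adj.items() for v in nbrs
        }
        assert got == expected

    def test_same_tool_edges_flag(self):
        calls = [
            make_ins("a", "t", "chr1", 100, 30),
            make_ins("b", "t", "chr1", 110, 30),
        ]
        g1 = build_call_graph([CallSet("t", calls)], global_criteria=DEFAULT_CRITERIA)
        g2 = build_call_graph(
            [CallSet("t", calls)], global_criteria=DEFAULT_CRITERIA,
            allow_same_tool=False,
        )
        assert g1.n_edges == 1 and g2.n_edges == 0

    def test_unknown_tool_without_global_criteria(self):
        cs = CallSet("mystery", [make_ins("a", "mystery", "chr1", 5, 30)])
        with pytest.raises(ConfigError):
            build_call_graph([cs], profiles={})

    def test_min_size_filter_excludes_small_known_lengths(self):
        calls = [
            make_ins("small", "t", "chr1", 100, 10),
            make_ins("kept", "t", "chr1", 200, 30),
            make_ins("nolen", "t", "chr1", 300, None),
        ]
        graph = build_call_graph([CallSet("t", calls)], global_criteria=DEFAULT_CRITERIA)
        assert set(graph.calls) == {"kept", "nolen"}


def graph_from_adjacency(n, edges):
    """CallGraph over n synthetic nodes with breakpoint = index."""
    calls = [make_ins(f"n{i:02d}", "t", "chr1", i + 1, 100) for i in range(n)]
    return CallGraph.from_edges(
        calls, [(f"n{u:02d}", f"n{v:02d}") for u, v in edges]
    )


def brute_force_maximal_cliques(n, edges):
    adj = [0] * n
    for u, v in edges:
        adj[u] |= 1 << v
        adj[v] |= 1 << u
    cliques = []
    for subset in range(1, 1 << n):
        members = [i for i in range(n) if subset >> i & 1]
        if all(adj[i] & subset == subset & ~(1 << i) for i in members):
            cliques.append(subset)
    maximal = [
        c for c in cliques
        if not any(c != d and c & d == c for d in cliques)
    ]
    return {
        frozenset(f"n{i:02d}" for i in range(n) if c >> i & 1) for c in maximal
    }


class TestMaximalCliques:
    def test_triangle(self):
        graph = graph_from_adjacency(3, [(0, 1), (1, 2), (0, 2)])
        assert enumerate_maximal_cliques(graph) == [frozenset({"n00", "n01", "n02"})]

    def test_path_shares_middle_node(self):
        graph = graph_from_adjacency(3, [(0, 1), (1, 2)])
        assert enumerate_maximal_cliques(graph) == [
            frozenset({"n00", "n01"}),
            frozenset({"n01", "n02"}),
        ]

    def test_isolated_nodes_are_singleton_cliques(self):
        graph = graph_from_adjacency(3, [])
        assert enumerate_maximal_cliques(graph) == [
            frozenset({"n00"}), frozenset({"n01"}), frozenset({"n02"})
        ]

    def test_matches_networkx_on_random_graphs(self, rng):
        """Independent library cross-check on 60 random graphs."""
        for _ in range(60):
            n = int(rng.integers(2, 15))
            density = float(rng.uniform(0.1, 0.9))
            edges = [
                (u, v)
                for u, v in itertools.combinations(range(n), 2)
                if rng.random() < density
            ]
            graph = graph_from_adjacency(n, edges)
            ours = set(enumerate_maximal_cliques(graph))
            g = nx.Graph()
            g.add_nodes_from(f"n{i:02d}" for i in range(n))
            g.add_edges_from(
                (f"n{u:02d}", f"n{v:02d}") for u, v in edges
            )
            theirs = {frozenset(c) for c in nx.find_cliques(g)}
            assert ours == theirs

    def test_deterministic_output_order(self, rng):
        edges = [(0, 1), (1, 2), (2, 3), (0, 2), (1, 3)]
        graph = graph_from_adjacency(4, edges)
        first = enumerate_maximal_cliques(graph)
        assert first == enumerate_maximal_cliques(graph)
        starts = [min(c) for c in first]
        assert starts == sorted(starts)


class TestMergeCliques:
    def make_profiles(self):
        return {
            "sr": ToolProfile.for_method("sr", MethodClass.SPLIT_READ),
            "is": ToolProfile.for_method("is", MethodClass.INTERNAL_SEGMENT),
        }

    def test_singleton_clique_is_identity(self):
        call = make_del("a", "sr", "chr1", 971, 1030)
        graph = CallGraph.from_edges([call], [])
        (m,) = merge_cliques([frozenset({"a"})], graph, self.make_profiles())
        assert (m.consensus_breakpoint, m.consensus_length, m.support) == (
            call.breakpoint, call.length, 1,
        )
        assert m.representative_tool == "sr"

    def test_best_rank_member_supplies_consensus(self):
        sr = make_ins("a", "sr", "chr1", 1000, 100)
        iseg = make_ins("b", "is", "chr1", 1030, 110)
        graph = CallGraph.from_edges([sr, iseg], [("a", "b")])
        (m,) = merge_cliques([frozenset({"a", "b"})], graph, self.make_profiles())
        assert (m.consensus_breakpoint, m.consensus_length) == (1000, 100)
        assert m.representative_tool == "sr"
        assert m.tools == ("is", "sr") and m.support == 2

    def test_equal_rank_uses_lower_median(self):
        calls = [
            make_ins("a", "t1", "chr1", 100, 30),
            make_ins("b", "t2", "chr1", 110, 34),
            make_ins("c", "t3", "chr1", 120, 38),
        ]
        graph = CallGraph.from_edges(calls, [("a", "b"), ("b", "c"), ("a", "c")])
        (m,) = merge_cliques([frozenset({"a", "b", "c"})], graph)
        assert m.consensus_breakpoint == 110
        assert m.consensus_length == 34
        # even count: lower median
        graph2 = CallGraph.from_edges(calls[:2], [("a", "b")])
        (m2,) = merge_cliques([frozenset({"a", "b"})], graph2)
        assert (m2.consensus_breakpoint, m2.consensus_length) == (100, 30)

    def test_unknown_length_never_becomes_consensus(self):
        calls = [
            make_ins("a", "sr", "chr1", 1000, None),
            make_ins("b", "is", "chr1", 1010, 80),
        ]
        graph = CallGraph.from_edges(calls, [("a", "b")])
        (m,) = merge_cliques([frozenset({"a", "b"})], graph, self.make_profiles())
        assert m.consensus_breakpoint == 1000  # split-read wins position
        assert m.consensus_length == 80       # but length from the IS member

    def test_greedy_disjoint_covers_and_partitions(self, rng):
        """Member sets are pairwise disjoint and cover every node."""
        for _ in range(30):
            n = int(rng.integers(2, 14))
            edges = [
                (u, v)
                for u, v in itertools.combinations(range(n), 2)
                if rng.random() < 0.4
            ]
            graph = graph_from_adjacency(n, edges)
            cliques = enumerate_maximal_cliques(graph)
            merged = merge_cliques(cliques, graph, policy="greedy_disjoint")
            seen = [cid for m in merged for cid in m.member_ids]
            assert len(seen) == len(set(seen)) == n

    def test_all_cliques_policy_keeps_overlaps(self):
        graph = graph_from_adjacency(3, [(0, 1), (1, 2)])
        cliques = enumerate_maximal_cliques(graph)
        merged = merge_cliques(cliques, graph, policy="all_cliques")
        assert len(merged) == 2
        members = [m.member_ids for m in merged]
        assert ("n00", "n01") in members and ("n01", "n02") in members

    def test_permutation_invariance(self, rng):
        """Shuffling input call order changes nothing in the merged output."""
        profiles = self.make_profiles()
        calls = [
            random_call(rng, f"c{i}", ("sr", "is")[i % 2], max_pos=3000, max_len=120)
            for i in range(80)
        ]
        def run(order):
            cs_sr = CallSet("sr", [c for c in order if c.tool_id == "sr"])
            cs_is = CallSet("is", [c for c in order if c.tool_id == "is"])
            return merge_callsets([cs_sr, cs_is], profiles=profiles, min_size=0)

        baseline = run(calls)
        for _ in range(3):
            shuffled = list(calls)
            random.Random(int(rng.integers(0, 2**31))).shuffle(shuffled)
            merged = run(shuffled)
            assert [
                (m.member_ids, m.consensus_breakpoint, m.consensus_length)
                for m in merged
            ] == [
                (m.member_ids, m.consensus_breakpoint, m.consensus_length)
                for m in baseline
            ]


class TestGuideline:
    def test_default_window_probability_small_for_random_call_layers(
        self, standard_scenario
    ):
        """The null model's premise holds for the uniformly placed
        false-positive layers of the standard scenario: at the default
        50 bp criterion their pairwise collision probability stays below
        0.01."""
        g = sum(standard_scenario["chrom_lengths"].values())
        fp_counts = [
            int(round(spec.fp_per_mb * g / 1e6))
            for spec in standard_scenario["specs"]
        ]
        for k1, k2 in itertools.combinations(fp_counts, 2):
            assert random_merge_probability(k1, k2, g, 50) <= 0.01
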