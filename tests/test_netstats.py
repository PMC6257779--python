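"""Statistics panel against hand computations and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import _oracles as oracle
from conftest import network_from_indices
from lagnet import (
    InsufficientDataError,
    RegulatoryNetwork,
    betweenness,
    centralization,
    clustering_coefficient,
    degree_metrics,
    fit_power_law,
    max_vulnerability,
    network_summary,
    path_metrics,
)


class TestDegreeMetrics:
    def test_average_degree_is_twice_edges_over_nodes(self):
        ids = tuple(f"g{k}" for k in range(800))
        edges = {}
        k = 0
        for i in range(800):
            for j in range(800):
                if i != j and k < 447:
                    edges[(ids[i], ids[j])] = None
                    k += 1
        net = RegulatoryNetwork(ids, edges)
        assert degree_metrics(net)["K"] == pytest.approx(1.1175, abs=1e-12)

    def test_edgeless_network(self):
        net = RegulatoryNetwork(tuple("abcde"))
        deg = degree_metrics(net)
        assert (deg["K"], deg["N0"], deg["Rn"]) == (0.0, 5, 0)

    def test_directed_triangle(self):
        net = RegulatoryNetwork.from_edge_list(
            "abc", [("a", "b"), ("b", "c"), ("c", "a")]
        )
        deg = degree_metrics(net)
        assert all(deg["indegree"][g] == 1 and deg["outdegree"][g] == 1 for g in "abc")
        assert deg["K"] == 2.0


class TestPathMetrics:
    def test_path_abc_by_hand(self, path_abc):
        m = path_metrics(path_abc)
        assert m["Dia"] == 2
        assert m["l"] == pytest.approx((1 + 1 + 2) / 3)
        assert m["E"] == pytest.approx((1 + 1 + 0.5) / 6)

    def test_complete_digraph_all_distances_one(self):
        ids = tuple("abcd")
        edges = {(u, v): None for u in ids for v in ids if u != v}
        m = path_metrics(RegulatoryNetwork(ids, edges))
        assert (m["Dia"], m["l"], m["E"]) == (1.0, 1.0, 1.0)

    def test_no_edges_flags_undefined(self):
        m = path_metrics(RegulatoryNetwork(tuple("ab")))
        assert (m["Dia"], m["l"], m["E"]) == (0.0, 0.0, 0.0)
        assert not m["path_metrics_defined"]


class TestBetweenness:
    def test_path_abc(self, path_abc):
        b = betweenness(path_abc)
        assert (b["a"], b["b"], b["c"]) == (0.0, 1.0, 0.0)

    def test_directed_four_cycle_by_enumeration(self):
        """Each node lies on one distance-2 and two distance-3 geodesics."""
        edges = {(0, 1), (1, 2), (2, 3), (3, 0)}
        expected = oracle.betweenness_by_enumeration(4, edges)
        assert expected == [3.0, 3.0, 3.0, 3.0]
        b = betweenness(network_from_indices(4, edges))
        assert [b[f"n{k}"] for k in range(4)] == expected


class TestClusteringAndCentralization:
    def test_triangle_any_orientation_is_fully_clustered(self):
        net = RegulatoryNetwork.from_edge_list(
            "abc", [("a", "b"), ("c", "b"), ("a", "c")]
        )
        assert clustering_coefficient(net) == 1.0

    def test_star_has_no_closed_triplets_and_maximal_centralization(self):
        ids = ("hub", "l1", "l2", "l3", "l4")
        edges = {}
        for leaf in ids[1:]:
            edges[("hub", leaf)] = None
            edges[(leaf, "hub")] = None
        net = RegulatoryNetwork(ids, edges)
        assert clustering_coefficient(net) == 0.0
        assert centralization(net) == pytest.approx(1.0)

    def test_regular_ring_has_zero_centralization(self):
        ids = tuple(f"n{k}" for k in range(6))
        edges = {(ids[k], ids[(k + 1) % 6]): None for k in range(6)}
        assert centralization(RegulatoryNetwork(ids, edges)) == 0.0


class TestMaxVulnerability:
    def test_path_abc_loses_everything_without_middle(self, path_abc):
        assert max_vulnerability(path_abc) == pytest.approx(1.0)

    def test_complete_digraph_is_invulnerable(self):
        ids = tuple("abcd")
        edges = {(u, v): None for u in ids for v in ids if u != v}
        assert max_vulnerability(RegulatoryNetwork(ids, edges)) == pytest.approx(0.0)


class TestOracleEquivalence:
    """All graph statistics match naive brute-force recomputation on random
    small digraphs (Floyd-Warshall distances, exhaustive geodesic and triple
    enumeration, per-node efficiency recomputation)."""

    def test_thirty_random_digraphs(self, rng):
        for _ in range(30):
            n, edges = oracle.random_digraph(rng)
            net = network_from_indices(n, edges)
            dia, avg, eff = oracle.path_stats(n, edges)
            m = path_metrics(net)
            assert m["Dia"] == pytest.approx(dia, abs=1e-12)
            assert m["l"] == pytest.approx(avg, abs=1e-12)
            assert m["E"] == pytest.approx(eff, abs=1e-12)
            assert clustering_coefficient(net) == pytest.approx(
                oracle.transitivity_by_enumeration(n, edges), abs=1e-12
            )
            assert max_vulnerability(net) == pytest.approx(
                oracle.max_vulnerability_by_recomputation(n, edges), abs=1e-12
            )

    def test_betweenness_matches_geodesic_enumeration(self, rng):
        for _ in range(30):
            n, edges = oracle.random_digraph(rng, n_max=7)
            b = betweenness(network_from_indices(n, edges))
            expected = oracle.betweenness_by_enumeration(n, edges)
            for k in range(n):
                assert b[f"n{k}"] == pytest.approx(expected[k], abs=1e-9)


class TestNetworkSummary:
    def test_edgeless_row(self):
        row = network_summary(RegulatoryNetwork(tuple("abcd")), label="empty")
        assert (row.K, row.Rn, row.N0, row.E, row.Vu, row.CC) == (0, 0, 4, 0, 0, 0)

    def test_k_rn_identity_on_random_networks(self, rng):
        for _ in range(10):
            n, edges = oracle.random_digraph(rng)
            row = network_summary(network_from_indices(n, edges))
            assert row.K == pytest.approx(2 * row.Rn / n, abs=1e-12)

    def test_path_fixture_row_composes_per_metric_results(self, path_abc):
        row = network_summary(path_abc, label="path")
        assert row.Dia == 2 and row.Rn == 2 and row.N0 == 0
        assert row.E == pytest.approx(2.5 / 6)
        assert row.Vu == pytest.approx(1.0)

    def test_metrics_invariant_under_relabeling(self, rng):
        n, edges = oracle.random_digraph(rng)
        net = network_from_indices(n, edges)
        perm = rng.permutation(n)
        ids2 = tuple(f"x{perm[k]}" for k in range(n))
        net2 = RegulatoryNetwork(
            ids2, {(ids2[i], ids2[j]): None for i, j in edges}
        )
        a, b = network_summary(net), network_summary(net2)
        for col in ("K", "Dia", "l", "N0", "Rn", "E", "Vu", "CC", "Ce"):
            assert getattr(a, col) == pytest.approx(getattr(b, col), abs=1e-12)

    def test_removing_an_edge_never_helps_connectivity(self, rng):
        for _ in range(10):
            n, edges = oracle.random_digraph(rng)
            if not edges:
                continue
            net = network_from_indices(n, edges)
            row = network_summary(net)
            victim = sorted(edges)[0]
            sub = network_from_indices(n, edges - {victim})
            row2 = network_summary(sub)
            assert row2.E <= row.E + 1e-12
            assert row2.Rn == row.Rn - 1
            assert row2.K <= row.K
            assert row2.N0 >= row.N0


class TestPowerLawFit:
    def test_recovers_exponent_two(self):
        hist = {d: round(1000 * d**-2.0) for d in range(1, 11)}
        fit = fit_power_law(hist)
        assert fit.slope == pytest.approx(-2.0, abs=0.05)
        assert fit.r_squared >= 0.999

    def test_flat_histogram_has_zero_slope(self):
        fit = fit_power_law({d: 5 for d in range(1, 11)})
        assert fit.slope == pytest.approx(0.0, abs=0.05)

    def test_single_degree_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_power_law({3: 10})

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_degree_zero_nodes_never_enter_the_fit(self, seed):
        rng = np.random.default_rng(seed)
        counts = {int(d): int(c) for d, c in
                  zip(rng.integers(1, 20, 5), rng.integers(1, 50, 5))}
        if len(counts) < 2:
            return
        with_zero = dict(counts)
        with_zero[0] = 1000
        assert fit_power_law(counts) == fit_power_law(with_zero)
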