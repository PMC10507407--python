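import math

import numpy as np
import pytest

from osteonet.network_io import InteractionNetwork
from osteonet.topology import (
    average_clustering,
    betweenness_centrality,
    closeness_centrality,
    compute_topology,
    eccentricity,
    node_degree,
)

from _naive import naive_topology, random_connected_adj
from conftest import build_net, complete, cycle


def adj_to_net(adj):
    net = InteractionNetwork()
    for v in adj:
        net.add_node(f"n{v}")
    for a in adj:
        for b in adj[a]:
            if a < b:
                net.add_edge(f"n{a}", f"n{b}", 0.95)
    return net


class TestDegree:
    def test_triangle_and_path(self, triangle, path3):
        assert node_degree(triangle, "A") == 2
        assert node_degree(path3, "B") == 2
        assert node_degree(path3, "A") == 1

    def test_unknown_node_raises(self, triangle):
        with pytest.raises(KeyError):
            node_degree(triangle, "Z")

    def test_handshake_lemma_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            net = adj_to_net(random_connected_adj(rng))
            assert sum(net.degree(v) for v in net.node_ids()) == 2 * net.n_edges


class TestClosedForms:
    """Analytic centrality values for path, star, cycle, and complete graphs."""

    def test_path_interior_carries_all_betweenness(self, path3):
        bc = betweenness_centrality(path3)
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_center_carries_every_leaf_pair(self, star4):
        bc = betweenness_centrality(star4)
        assert bc["c"] == pytest.approx(3.0)  # C(3,2) leaf pairs
        assert all(bc[f"l{i}"] == 0.0 for i in (1, 2, 3))

    def test_four_cycle_splits_antipodal_pair(self):
        bc = betweenness_centrality(cycle(4))
        assert all(v == pytest.approx(0.5) for v in bc.values())

    def test_path_eccentricity_and_closeness(self, path3):
        ecc = eccentricity(path3)
        assert ecc == {"A": 2, "B": 1, "C": 2}
        cc = closeness_centrality(path3)
        assert cc["A"] == pytest.approx(2 / 3)
        assert cc["B"] == pytest.approx(1.0)

    def test_complete_graph_is_fully_central(self):
        k5 = complete(5)
        assert set(eccentricity(k5).values()) == {1}
        assert all(v == pytest.approx(1.0) for v in closeness_centrality(k5).values())

    def test_five_cycle_eccentricity(self):
        assert set(eccentricity(cycle(5)).values()) == {2}

    def test_star_closeness(self, star4):
        cc = closeness_centrality(star4)
        assert cc["c"] == pytest.approx(1.0)
        assert cc["l1"] == pytest.approx(3 / 5)

    def test_clustering_triangle_path_and_k4_minus_edge(self, triangle, path3):
        assert average_clustering(triangle) == pytest.approx(1.0)
        assert average_clustering(path3) == 0.0
        k4_minus = build_net(
            [("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
        )
        assert average_clustering(k4_minus) == pytest.approx(5 / 6)


class TestComputeTopology:
    def test_mean_degree_is_2e_over_n(self):
        from osteonet.synthetic_data import PlantedGraphSpec, gen_planted_graph

        net, _ = gen_planted_graph(PlantedGraphSpec(seed=2))
        topo = compute_topology(net)
        assert topo.mean_degree == pytest.approx(2 * 42 / 24) == 3.5

    def test_triangle_globals(self, triangle):
        topo = compute_topology(triangle)
        assert topo.mean_degree == pytest.approx(2.0)
        assert topo.avg_clustering == pytest.approx(1.0)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            compute_topology(InteractionNetwork())

    def test_matches_naive_oracle_on_random_small_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            adj = random_connected_adj(rng)
            topo = compute_topology(adj_to_net(adj))
            oracle = naive_topology(adj)
            for nt in topo.per_node:
                v = int(nt.identifier[1:])
                assert nt.k == oracle["k"][v]
                assert nt.ecc == oracle["ecc"][v]
                assert nt.bc == pytest.approx(oracle["bc"][v], abs=1e-9)
                assert nt.cc == pytest.approx(oracle["cc"][v], abs=1e-9)
            assert topo.avg_clustering == pytest.approx(oracle["acc"], abs=1e-9)

    def test_matches_networkx_on_larger_random_graphs(self):
        nx = pytest.importorskip("networkx")
        for seed in range(5):
            g = nx.gnp_random_graph(30, 0.15, seed=seed)
            if not nx.is_connected(g):
                g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
            net = InteractionNetwork()
            for v in g.nodes:
                net.add_node(f"n{v:02d}")
            for a, b in g.edges:
                net.add_edge(f"n{a:02d}", f"n{b:02d}", 0.95)
            topo = compute_topology(net)
            bc = nx.betweenness_centrality(g, normalized=False)
            cc = nx.closeness_centrality(g, wf_improved=False)
            ecc = nx.eccentricity(g)
            for nt in topo.per_node:
                v = int(nt.identifier[1:])
                assert nt.bc == pytest.approx(bc[v], abs=1e-9)
                assert nt.cc == pytest.approx(cc[v], abs=1e-9)
                assert nt.ecc == ecc[v]
            assert topo.avg_clustering == pytest.approx(
                nx.average_clustering(g), abs=1e-9
            )


class TestInvariants:
    def test_leaf_betweenness_is_zero_and_bc_nonnegative(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            net = adj_to_net(random_connected_adj(rng))
            bc = betweenness_centrality(net)
            for v in net.node_ids():
                assert bc[v] >= 0.0
                if net.degree(v) == 1:
                    assert bc[v] == 0.0

    def test_tree_betweenness_sums_to_excess_path_length(self):
        # on a tree each pair has one path, so sum BC = sum over pairs (d-1)
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            net = InteractionNetwork()
            for v in range(1, n):
                net.add_edge(f"t{v:02d}", f"t{int(rng.integers(0, v)):02d}", 0.9)
            bc = betweenness_centrality(net)
            adj = {
                int(v[1:]): {int(u[1:]) for u in net.neighbors(v)}
                for v in net.node_ids()
            }
            from _naive import bfs_distances

            pair_excess = 0.0
            nodes = sorted(adj)
            for i, s in enumerate(nodes):
                d = bfs_distances(adj, s)
                pair_excess += sum(d[t] - 1 for t in nodes[i + 1 :])
            assert sum(bc.values()) == pytest.approx(pair_excess, abs=1e-9)

    def test_radius_diameter_bounds_per_component(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            net = adj_to_net(random_connected_adj(rng))
            eccs = list(eccentricity(net).values())
            radius, diameter = min(eccs), max(eccs)
            assert radius <= diameter <= 2 * radius

    def test_closeness_in_unit_interval_with_unit_iff_adjacent_to_all(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            net = adj_to_net(random_connected_adj(rng))
            cc = closeness_centrality(net)
            for v in net.node_ids():
                assert 0.0 <= cc[v] <= 1.0
                is_universal = net.degree(v) == net.n_nodes - 1
                assert (cc[v] == 1.0) == is_universal

    def test_relabeling_permutes_per_node_and_fixes_globals(self):
        rng = np.random.default_rng(31)
        adj = random_connected_adj(rng)
        net = adj_to_net(adj)
        perm = {f"n{v}": f"z{9 - v}" for v in adj}
        relabeled = InteractionNetwork()
        for e in net.edges():
            relabeled.add_edge(perm[e.endpoint_a], perm[e.endpoint_b], e.combined_score)
        t1, t2 = compute_topology(net), compute_topology(relabeled)
        assert t1.mean_degree == t2.mean_degree
        assert t1.avg_clustering == pytest.approx(t2.avg_clustering)
        for nt in t1.per_node:
            other = t2.node(perm[nt.identifier])
            assert (nt.k, nt.ecc) == (other.k, other.ecc)
            assert nt.bc == pytest.approx(other.bc)
            assert nt.cc == pytest.approx(other.cc)

    def test_disconnected_input_handled_per_component(self):
        net = build_net([("A", "B"), ("C", "D"), ("D", "E")], nodes=["F"])
        topo = compute_topology(net)
        f = topo.node("F")
        assert f.ecc == 0 and f.cc == 0.0
        assert topo.node("A").ecc == 1
        assert topo.node("C").ecc == 2
        comps = {nt.component for nt in topo.per_node}
        assert len(comps) == 3
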