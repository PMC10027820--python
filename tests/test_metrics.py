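import numpy as np
import pytest

import networkx as nx

from scanpathnet import apply_mask, from_edges
from scanpathnet.metrics import (
    UndefinedMetricError,
    characteristic_path_length,
    classify_topology,
    clustering_coefficient,
    density,
    freeman_centralization,
    global_efficiency,
    metric_set,
    random_reference,
    shortest_distances,
    small_worldness,
    transitivity,
)

from conftest import complete_graph


def lattice_network(n=100, k=6, p=0.1, seed=0):
    """Watts-Strogatz ring lattice as a reciprocal unit-weight digraph."""
    g = nx.watts_strogatz_graph(n, k, p, seed=seed)
    edges = [(str(u), str(v), 1.0) for u, v in g.edges]
    edges += [(str(v), str(u), 1.0) for u, v in g.edges]
    return from_edges(edges, nodes=[str(i) for i in range(n)])


class TestDensity:
    def test_complete_directed_graph_is_maximally_dense(self):
        assert density(complete_graph(6)) == 1.0

    def test_printed_example_matrix(self, table1_directed):
        assert density(table1_directed) == pytest.approx(14 / 56)

    def test_edgeless_graph(self):
        assert density(from_edges([], nodes=list("abcde"))) == 0.0

    def test_single_node_undefined(self):
        with pytest.raises(UndefinedMetricError):
            density(from_edges([], nodes=["a"]))


class TestCentralization:
    def test_star_is_maximally_centralized(self):
        star = from_edges([("h", f"l{i}", 1.0) for i in range(4)])
        assert freeman_centralization(star) == 1.0

    def test_unit_path_graph(self):
        path4 = from_edges([("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)])
        assert freeman_centralization(path4) == pytest.approx(1 / 3)

    def test_degree_regular_graph_is_uncentralized(self):
        assert freeman_centralization(complete_graph(5)) == 0.0

    def test_too_small_undefined(self):
        with pytest.raises(UndefinedMetricError):
            freeman_centralization(from_edges([("a", "b", 1.0)]))

    def test_binarized_score_bounded_on_weighted_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            edges = [
                (str(i), str(j), float(rng.uniform(0.5, 9)))
                for i in range(n)
                for j in range(n)
                if i != j and rng.random() < 0.5
            ]
            if not edges:
                continue
            c = freeman_centralization(
                from_edges(edges, nodes=[str(i) for i in range(n)]), binarize=True
            )
            assert 0.0 <= c <= 1.0


class TestTopologyBands:
    @pytest.mark.parametrize(
        "c, label",
        [
            (0.0, "linear"),
            (0.1, "linear"),
            (0.2, "hierarchical"),
            (0.35, "hierarchical"),
            (0.45, "network"),
            (0.6, "star"),
            (1.0, "star"),
        ],
    )
    def test_band_assignment(self, c, label):
        assert classify_topology(c) == label

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert classify_topology(1.4) == "star"


class TestTransitivity:
    def test_complete_symmetric_graph_is_fully_transitive(self):
        edges = [
            (str(i), str(j), 1.0) for i in range(4) for j in range(4) if i != j
        ]
        assert transitivity(from_edges(edges)) == pytest.approx(1.0)

    def test_path_graph_has_no_triangles(self):
        assert transitivity(from_edges([("a", "b", 1.0), ("b", "c", 1.0)])) == 0.0

    def test_directed_weighted_three_cycle(self):
        # hand enumeration: sum t_i = 6, denominator = 14
        net = from_edges([("a", "b", 2.0), ("b", "c", 1.0), ("c", "a", 1.0)])
        assert transitivity(net) == pytest.approx(3 / 7)

    def test_no_connected_triples_returns_zero_with_warning(self):
        net = from_edges([("a", "b", 0.5)], nodes=list("abc"))
        with pytest.warns(UserWarning):
            assert transitivity(net) == 0.0


class TestClustering:
    def test_reciprocal_unit_triangle_matches_hand_value(self):
        # per node: t = 8, k = 4 -> 2t/(k(k-1)) = 4/3
        edges = [(a, b, 1.0) for a in "abc" for b in "abc" if a != b]
        assert clustering_coefficient(from_edges(edges)) == pytest.approx(4 / 3)

    def test_one_directional_cycle_triangle(self):
        net = from_edges([("a", "b", 1.0), ("b", "c", 1.0), ("c", "a", 1.0)])
        assert clustering_coefficient(net) == pytest.approx(1.0)

    def test_star_has_no_clustering(self):
        star = from_edges([("h", f"l{i}", 1.0) for i in range(4)])
        assert clustering_coefficient(star) == 0.0

    def test_isolated_nodes_contribute_zero(self):
        assert clustering_coefficient(from_edges([], nodes=list("abc"))) == 0.0


class TestShortestDistances:
    def test_directed_chain(self):
        dm = shortest_distances(from_edges([("a", "b", 1.0), ("b", "c", 1.0)]))
        assert dm.distance("a", "c") == 2.0
        assert dm.distance("c", "a") == np.inf

    def test_strong_two_hop_route_beats_weak_direct_edge(self):
        net = from_edges([("a", "b", 1.0), ("a", "x", 4.0), ("x", "b", 4.0)])
        assert shortest_distances(net).distance("a", "b") == pytest.approx(0.5)

    def test_single_node(self):
        dm = shortest_distances(from_edges([], nodes=["a"]))
        assert dm.d.shape == (1, 1) and dm.distance("a", "a") == 0.0


class TestGlobalEfficiency:
    def test_complete_graph_is_maximally_efficient(self):
        assert global_efficiency(complete_graph(8)) == 1.0

    def test_edgeless_graph_has_zero_efficiency(self):
        assert global_efficiency(from_edges([], nodes=[str(i) for i in range(8)])) == 0.0

    def test_reciprocal_unit_path_of_three(self):
        edges = [("a", "b", 1.0), ("b", "a", 1.0), ("b", "c", 1.0), ("c", "b", 1.0)]
        assert global_efficiency(from_edges(edges)) == pytest.approx(5 / 6)

    def test_single_node_undefined(self):
        with pytest.raises(UndefinedMetricError):
            global_efficiency(from_edges([], nodes=["a"]))


class TestCharacteristicPathLength:
    def test_complete_unit_graph(self):
        assert characteristic_path_length(complete_graph(5)) == 1.0

    def test_as_printed_mode_equals_global_efficiency_exactly(self, table1_directed):
        assert characteristic_path_length(
            table1_directed, mode="as_printed"
        ) == global_efficiency(table1_directed)

    def test_directed_chain_mean_over_reachable_pairs(self):
        net = from_edges([("a", "b", 1.0), ("b", "c", 1.0)])
        assert characteristic_path_length(net) == pytest.approx((1 + 1 + 2) / 3)

    def test_no_reachable_pairs_undefined(self):
        with pytest.raises(UndefinedMetricError):
            characteristic_path_length(from_edges([], nodes=list("ab")))


class TestRandomReference:
    def test_complete_graph_forces_identical_references(self):
        net = complete_graph(5)
        ens = random_reference(net, n_refs=5, seed=1)
        assert ens.c_rand == pytest.approx(clustering_coefficient(net))
        assert ens.l_rand == pytest.approx(characteristic_path_length(net))

    def test_same_seed_reproduces_ensemble(self):
        net = lattice_network(n=30, k=4, seed=2)
        a = random_reference(net, n_refs=4, seed=7)
        b = random_reference(net, n_refs=4, seed=7)
        assert [r.weights for r in a.references] == [r.weights for r in b.references]

    def test_references_preserve_node_and_edge_counts_and_density(self):
        net = lattice_network(n=25, k=4, seed=3)
        ens = random_reference(net, n_refs=20, seed=0)
        for ref in ens.references:
            assert ref.n == net.n and ref.n_edges == net.n_edges
            assert density(ref) == pytest.approx(density(net))

    def test_bad_n_refs_rejected(self):
        with pytest.raises(ValueError):
            random_reference(complete_graph(4), n_refs=0)


class TestSmallWorldness:
    def test_complete_graph_self_normalizes_to_one(self):
        assert small_worldness(complete_graph(5), n_refs=3, seed=0) == pytest.approx(1.0)

    def test_rewired_ring_lattice_is_small_world(self):
        s = small_worldness(lattice_network(), n_refs=20, seed=0)
        assert s > 1.0

    def test_deterministic_given_seed(self):
        net = lattice_network(n=40, k=4, seed=5)
        assert small_worldness(net, n_refs=5, seed=3) == small_worldness(
            net, n_refs=5, seed=3
        )


class TestMetricSet:
    def test_printed_matrix_bundle(self, table1_directed):
        ms = metric_set(table1_directed, n_refs=5, seed=0)
        assert ms.density == pytest.approx(0.25)
        assert ms.n_nodes == 8
        assert ms.l_mode == "mean_distance"

    def test_empty_masked_network_flags_everything(self):
        empty = apply_mask(from_edges([("a", "b", 0.1)]))
        ms = metric_set(empty)
        assert ms.density is None and "density" in ms.flags
        assert ms.small_worldness is None

    def test_same_seed_gives_identical_results(self, table1_directed):
        a = metric_set(table1_directed, n_refs=5, seed=9)
        b = metric_set(table1_directed, n_refs=5, seed=9)
        assert a == b


def test_all_metrics_invariant_under_node_relabeling():
    rng = np.random.default_rng(42)
    base_nodes = list("abcdefg")
    edges = [
        (base_nodes[i], base_nodes[j], float(rng.integers(1, 5)))
        for i in range(7)
        for j in range(7)
        if i != j and rng.random() < 0.4
    ]
    net = from_edges(edges, nodes=base_nodes)
    mapping = dict(zip(base_nodes, ["n%d" % i for i in rng.permutation(7)]))
    relabeled = from_edges(
        [(mapping[i], mapping[j], w) for i, j, w in edges],
        nodes=[mapping[n] for n in base_nodes],
    )
    for fn in (density, freeman_centralization, transitivity, global_efficiency,
               clustering_coefficient):
        assert fn(net) == pytest.approx(fn(relabeled))
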