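import itertools

import networkx as nx
import numpy as np
import pytest

from oracles import best_partition_exhaustive, modularity_double_sum
from proxsoc.errors import (
    ConfigurationError,
    EmptyNetworkError,
    PartitionError,
    UndefinedMetricError,
)
from proxsoc.network import (
    Partition,
    RadiusClass,
    WeightedNetwork,
    build_network,
    degree_stats,
    density,
    modularity,
    network_metrics,
    pairing_success,
    potts_communities,
    walktrap,
    write_edgelist_csv,
    write_graphml,
)
from proxsoc.records import ScanRecord, Timestamp


def scan(female, day, ring2=(), ring5=(), minute=400):
    return ScanRecord(
        focal_female=female, time=Timestamp(day, minute),
        males_2m=frozenset(ring2), males_5m=frozenset(ring5),
    )


def two_triangles():
    edges = [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
             ("x", "y", 1), ("y", "z", 1), ("x", "z", 1)]
    return WeightedNetwork.from_edges(edges)


def random_weighted_network(rng, n_max=8, p=0.5):
    while True:
        n = int(rng.integers(3, n_max + 1))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1_000_000_000)))
        if g.number_of_edges() >= 2:
            break
    edges = [(f"n{u}", f"n{v}", int(rng.integers(1, 12))) for u, v in g.edges]
    return WeightedNetwork.from_edges(edges)


class TestBuildNetwork:
    def test_weight_counts_co_scans(self):
        scans = [
            scan("F", 1, ring2={"A"}),
            scan("F", 2, ring2={"A"}),
            scan("F", 3, ring5={"A"}),
        ]
        net = build_network(scans, RadiusClass.TWO_M)
        assert net.weight("F", "A") == 2

    def test_five_m_is_cumulative(self):
        scans = [scan("F", 1, ring5={"B"}), scan("F", 2, ring2={"A"})]
        two = build_network(scans, RadiusClass.TWO_M)
        five = build_network(scans, RadiusClass.FIVE_M)
        assert "B" not in two.graph
        assert five.weight("F", "B") == 1
        assert five.weight("F", "A") == 1

    def test_five_m_edges_superset_of_two_m(self, default_sim):
        config, truth, states, focals, adlib = default_sim
        all_scans = [s for f in focals for s in f.scans]
        rng = np.random.default_rng(0)
        for _ in range(100):
            idx = rng.choice(len(all_scans), size=200, replace=False)
            subset = [all_scans[i] for i in idx]
            two = build_network(subset, RadiusClass.TWO_M)
            five = build_network(subset, RadiusClass.FIVE_M)
            assert set(map(frozenset, two.graph.edges)) <= set(
                map(frozenset, five.graph.edges))
            assert five.n_dyads >= two.n_dyads

    def test_window_filter_and_empty_error(self):
        scans = [scan("F", 5, ring2={"A"})]
        with pytest.raises(EmptyNetworkError):
            build_network(scans, RadiusClass.TWO_M, window=(10, 20))

    def test_isolated_individuals_dropped(self):
        scans = [scan("F", 1, ring2={"A"}), scan("G", 1)]
        net = build_network(scans, RadiusClass.TWO_M)
        assert "G" not in net.graph


class TestDensityDegree:
    @staticmethod
    def _graph_with(n_nodes, n_edges):
        # a cycle (no isolates) plus deterministic chords up to n_edges
        edges = [(i, (i + 1) % n_nodes) for i in range(n_nodes)]
        seen = set(map(frozenset, edges))
        step = 2
        while len(edges) < n_edges:
            for i in range(n_nodes):
                pair = frozenset((i, (i + step) % n_nodes))
                if len(pair) == 2 and pair not in seen:
                    seen.add(pair)
                    edges.append(tuple(sorted(pair)))
                    if len(edges) == n_edges:
                        break
            step += 1
        return WeightedNetwork.from_edges(
            [(f"n{u:02d}", f"n{v:02d}", 1) for u, v in edges])

    def test_28_nodes_91_edges(self):
        # the larger printed worked example: density 0.24, mean degree 6.5
        net = self._graph_with(28, 91)
        assert net.n_nodes == 28 and net.n_dyads == 91
        assert round(density(net), 2) == 0.24
        assert round(degree_stats(net).degree_mean, 1) == 6.5

    def test_24_nodes_48_edges(self):
        net = self._graph_with(24, 48)
        assert net.n_nodes == 24 and net.n_dyads == 48
        assert round(density(net), 2) == 0.17
        assert degree_stats(net).degree_mean == 4.0

    def test_complete_triangle_density_one(self):
        net = WeightedNetwork.from_edges([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        assert density(net) == 1.0

    def test_single_edge_degree(self):
        net = WeightedNetwork.from_edges([("a", "b", 3)])
        stats = degree_stats(net)
        assert stats.degree_mean == 1.0
        assert stats.degree_range == (1, 1)
        assert stats.strength_of == {"a": 3.0, "b": 3.0}

    def test_density_undefined_below_two_nodes(self):
        net = WeightedNetwork.from_edges([])
        with pytest.raises(UndefinedMetricError):
            density(net)

    def test_weights_do_not_change_density(self):
        light = WeightedNetwork.from_edges([("a", "b", 1), ("b", "c", 1)])
        heavy = WeightedNetwork.from_edges([("a", "b", 99), ("b", "c", 5)])
        assert density(light) == density(heavy)


class TestModularity:
    def test_single_community_q_zero(self):
        net = two_triangles()
        part = Partition.from_labels({n: 1 for n in net.nodes()})
        assert modularity(net, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_each_own_community(self):
        # frozen from the double-sum oracle on this 6-node graph
        net = two_triangles()
        labels = {"a": 1, "b": 1, "c": 1, "x": 2, "y": 2, "z": 2}
        assert modularity(net, Partition.from_labels(labels)) == pytest.approx(0.5)

    def test_singleton_partition_of_triangle(self):
        net = WeightedNetwork.from_edges([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        labels = {"a": 1, "b": 2, "c": 3}
        assert modularity(net, Partition.from_labels(labels)) == pytest.approx(-1 / 3)

    def test_uncovered_node_raises(self):
        net = two_triangles()
        with pytest.raises(PartitionError):
            modularity(net, Partition.from_labels({"a": 1}))

    def test_agrees_with_double_sum_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            net = random_weighted_network(rng)
            nodes = net.nodes()
            weight_of = {(u, v): w for u, v, w in net.graph.edges(data="weight")}
            labels = {n: int(rng.integers(1, 4)) for n in nodes}
            expected = modularity_double_sum(nodes, weight_of, labels)
            got = modularity(net, Partition.from_labels(labels))
            assert got == pytest.approx(expected, abs=1e-9)


class TestWalktrap:
    def test_two_cliques_single_bridge(self):
        edges = []
        for base in ("a", "b"):
            nodes = [f"{base}{i}" for i in range(4)]
            edges += [(u, v, 1) for u, v in itertools.combinations(nodes, 2)]
        edges.append(("a0", "b0", 1))
        net = WeightedNetwork.from_edges(edges)
        _, part = walktrap(net)
        assert part.n_communities == 2
        groups = {frozenset(c) for c in part.communities()}
        assert groups == {frozenset({"a0", "a1", "a2", "a3"}),
                          frozenset({"b0", "b1", "b2", "b3"})}
        # matches exhaustive modularity maximisation on the 8-node graph
        weight_of = {(u, v): w for u, v, w in net.graph.edges(data="weight")}
        best_q, _ = best_partition_exhaustive(net.nodes(), weight_of)
        assert modularity(net, part) == pytest.approx(best_q, abs=1e-9)

    def test_no_community_spans_components(self):
        net = WeightedNetwork.from_edges(
            [("a", "b", 2), ("b", "c", 1), ("x", "y", 5)])
        _, part = walktrap(net)
        comp1 = {part.community_of[n] for n in ("a", "b", "c")}
        comp2 = {part.community_of[n] for n in ("x", "y")}
        assert not (comp1 & comp2)

    def test_zero_edges_each_node_singleton(self):
        net = WeightedNetwork(graph=nx.empty_graph(0, create_using=nx.Graph),
                              radius_class=RadiusClass.TWO_M)
        net.graph.add_nodes_from(["a", "b"])
        _, part = walktrap(net)
        assert part.n_communities == 2

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        net = random_weighted_network(rng, n_max=10)
        assert walktrap(net)[1] == walktrap(net)[1]

    def test_invalid_walk_length(self):
        with pytest.raises(ConfigurationError):
            walktrap(two_triangles(), t=0)

    def test_recovers_units_on_simulated_network(self, default_sim):
        config, truth, states, focals, adlib = default_sim
        scans = [s for f in focals for s in f.scans]
        net = build_network(scans, RadiusClass.TWO_M, window=(1, 60))
        _, part = walktrap(net)
        primary = {f: truth.primary_on(f, 30) for f in truth.females}
        assert pairing_success(net, part, primary) >= 0.9


class TestPotts:
    def test_two_triangles_recovered(self):
        net = two_triangles()
        part = potts_communities(net, seed=0)
        groups = {frozenset(c) for c in part.communities()}
        assert groups == {frozenset({"a", "b", "c"}), frozenset({"x", "y", "z"})}
        assert modularity(net, part) == pytest.approx(0.5)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(9)
        net = random_weighted_network(rng, n_max=10)
        a = potts_communities(net, seed=3)
        b = potts_communities(net, seed=3)
        assert a == b

    def test_gamma_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            potts_communities(two_triangles(), gamma=0.0)

    def test_small_gamma_merges_everything(self):
        # gamma -> 0 removes the null-model penalty; connected graphs
        # collapse into one community
        net = two_triangles()
        net.graph.add_edge("c", "x", weight=1)
        part = potts_communities(net, gamma=1e-6, seed=0)
        assert part.n_communities == 1

    def test_agreement_with_walktrap_on_planted_two_blocks(self):
        agree = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            edges = []
            for block in ("a", "b"):
                nodes = [f"{block}{i}" for i in range(5)]
                for u, v in itertools.combinations(nodes, 2):
                    if rng.random() < 0.9:
                        edges.append((u, v, int(rng.integers(3, 8))))
            edges.append(("a0", "b0", 1))
            net = WeightedNetwork.from_edges(edges)
            _, wt = walktrap(net)
            pt = potts_communities(net, seed=seed, restarts=8)
            if wt == pt:
                agree += 1
        assert agree >= 0.95 * n_seeds


class TestPairingSuccess:
    def test_all_units_one_community_each(self):
        net = WeightedNetwork.from_edges([("F1", "M1", 5), ("F2", "M2", 5)])
        part = Partition.from_labels({"F1": 1, "M1": 1, "F2": 2, "M2": 2})
        assert pairing_success(net, part, {"F1": "M1", "F2": "M2"}) == 1.0

    def test_single_big_community_trivially_one(self):
        # degenerate case: a one-community partition always scores 1.0
        net = WeightedNetwork.from_edges([("F1", "M1", 5), ("F2", "M2", 5)])
        part = Partition.from_labels({n: 1 for n in net.nodes()})
        assert pairing_success(net, part, {"F1": "M2", "F2": "M1"}) == 1.0

    def test_missing_primary_counts_as_failure(self):
        net = WeightedNetwork.from_edges([("F1", "M1", 5)])
        part = Partition.from_labels({"F1": 1, "M1": 1})
        assert pairing_success(net, part, {"F1": "M9"}) == 0.0


class TestExports:
    def test_edgelist_and_graphml(self, tmp_path):
        scans = [scan("F", 1, ring2={"A"}), scan("F", 2, ring2={"A", "B"})]
        net = build_network(scans, RadiusClass.TWO_M)
        _, part = walktrap(net)
        write_edgelist_csv(tmp_path / "net.csv", net)
        write_graphml(tmp_path / "net.graphml", net, part)
        lines = (tmp_path / "net.csv").read_text().splitlines()
        assert lines[0] == "female,male,weight"
        assert "F,A,2" in lines
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_edges() == net.n_dyads

    def test_metrics_bundle(self):
        net = two_triangles()
        _, part = walktrap(net)
        metrics = network_metrics(net, {"walktrap": part})
        assert metrics.n_nodes == 6
        assert metrics.density == pytest.approx(6 / 15)
        assert metrics.modularity_q["walktrap"] == pytest.approx(0.5)
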