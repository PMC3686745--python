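import itertools
import math
from collections import deque

import networkx as nx
import numpy as np
import pytest

from coexnet import (
    InteractionNetwork,
    Partition,
    best_partition,
    edge_betweenness,
    modularity,
    ng_dendrogram,
)
from coexnet.communities import CommunitySet, Dendrogram

from conftest import make_net


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_edge_betweenness(g: nx.Graph) -> dict:
    """Enumerate every shortest path of every pair; split ties equally."""
    bt = {tuple(sorted(e, key=str)): 0.0 for e in g.edges()}

    def all_shortest_paths(src, dst):
        # BFS predecessor DAG, then recursive enumeration
        dist = {src: 0}
        preds = {src: []}
        q = deque([src])
        while q:
            u = q.popleft()
            for v in g[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    preds[v] = [u]
                    q.append(v)
                elif dist[v] == dist[u] + 1:
                    preds[v].append(u)
        if dst not in dist:
            return []
        paths = []

        def walk(v, tail):
            if v == src:
                paths.append([src] + tail)
                return
            for p in preds[v]:
                walk(p, [v] + tail)

        walk(dst, [])
        return paths

    for u, v in itertools.combinations(sorted(g.nodes, key=str), 2):
        paths = all_shortest_paths(u, v)
        if not paths:
            continue
        share = 1.0 / len(paths)
        for path in paths:
            for a, b in zip(path, path[1:]):
                bt[tuple(sorted((a, b), key=str))] += share
    return bt


def direct_count_modularity(g: nx.Graph, partition: Partition) -> float:
    """Q from intra-edge counts and community degree sums."""
    m = g.number_of_edges()
    q = 0.0
    for c in range(partition.k):
        members = {v for v, cc in partition.assignment.items() if cc == c}
        l_c = sum(1 for u, v in g.edges() if u in members and v in members)
        d_c = sum(d for v, d in g.degree() if v in members)
        q += l_c / m - (d_c / (2 * m)) ** 2
    return q


def all_partitions(items):
    """Every set partition of items (restricted growth strings)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def partition_from_blocks(blocks) -> Partition:
    return Partition(
        assignment={v: i for i, b in enumerate(blocks) for v in b}, k=len(blocks)
    )


# ---------------------------------------------------------------------------
# edge betweenness

class TestEdgeBetweenness:
    def test_path_graph(self, path_net):
        bt = edge_betweenness(path_net)
        assert bt[("A", "B")] == pytest.approx(2.0)
        assert bt[("B", "C")] == pytest.approx(2.0)

    def test_star_graph(self):
        net = make_net([("c", "a"), ("c", "b"), ("c", "d")])
        bt = edge_betweenness(net)
        assert all(v == pytest.approx(3.0) for v in bt.values())

    def test_four_cycle_splits_tied_paths(self):
        # opposite pairs have two equal shortest paths, 0.5 each; brute
        # force (and the distance-sum identity 4*1 + 2*2 = 8) gives 2.0
        net = make_net([(0, 1), (1, 2), (2, 3), (3, 0)])
        bt = edge_betweenness(net)
        oracle = brute_force_edge_betweenness(net.graph)
        assert bt == pytest.approx(oracle)
        assert all(v == pytest.approx(2.0) for v in bt.values())

    def test_empty_graph(self):
        assert edge_betweenness(InteractionNetwork(graph=nx.Graph(), tau=0.8)) == {}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 26))
        g = nx.gnp_random_graph(n, 2.5 / n, seed=seed)
        net = InteractionNetwork(graph=g, tau=0.8)
        bt = edge_betweenness(net)
        oracle = brute_force_edge_betweenness(g)
        for e in oracle:
            assert bt[e] == pytest.approx(oracle[e], abs=1e-9)

    def test_sum_equals_total_pairwise_distance(self):
        g = nx.gnp_random_graph(15, 0.25, seed=3)
        net = InteractionNetwork(graph=g, tau=0.8)
        total_bt = sum(edge_betweenness(net).values())
        total_dist = 0
        for comp in nx.connected_components(g):
            dist = dict(nx.all_pairs_shortest_path_length(g.subgraph(comp)))
            total_dist += sum(sum(d.values()) for d in dist.values()) / 2
        assert total_bt == pytest.approx(total_dist)


# ---------------------------------------------------------------------------
# modularity

class TestModularity:
    def test_single_community_is_zero(self, two_triangles_bridge):
        part = partition_from_blocks([list(two_triangles_bridge.graph.nodes)])
        assert modularity(part, two_triangles_bridge) == pytest.approx(0.0)

    def test_single_edge_singletons(self):
        net = make_net([("A", "B")])
        part = partition_from_blocks([["A"], ["B"]])
        assert modularity(part, net) == pytest.approx(-0.5)

    def test_two_triangles_bridge_split(self, two_triangles_bridge):
        part = partition_from_blocks([["a", "b", "c"], ["d", "e", "f"]])
        assert modularity(part, two_triangles_bridge) == pytest.approx(5 / 14)

    def test_empty_edge_set_errors(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        net = InteractionNetwork(graph=g, tau=0.8)
        with pytest.raises(ValueError, match="no edges"):
            modularity(partition_from_blocks([["a"], ["b"]]), net)

    def test_uncovered_vertex_errors(self, triangle_net):
        with pytest.raises(ValueError, match="cover"):
            modularity(partition_from_blocks([["a", "b"]]), triangle_net)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_direct_count_oracle_exhaustively(self, seed):
        g = nx.gnp_random_graph(6, 0.5, seed=seed)
        if g.number_of_edges() == 0:
            pytest.skip("no edges sampled")
        net = InteractionNetwork(graph=g, tau=0.8)
        for blocks in all_partitions(sorted(g.nodes)):
            part = partition_from_blocks(blocks)
            assert modularity(part, net) == pytest.approx(
                direct_count_modularity(g, part), abs=1e-12
            )

    def test_matches_networkx_on_8_vertex_graph(self):
        g = nx.gnp_random_graph(8, 0.4, seed=11)
        net = InteractionNetwork(graph=g, tau=0.8)
        rng = np.random.default_rng(11)
        for _ in range(50):
            labels = rng.integers(0, 3, size=8)
            blocks = [
                [v for v, l in zip(sorted(g.nodes), labels) if l == c]
                for c in sorted(set(labels))
            ]
            part = partition_from_blocks(blocks)
            expected = nx.community.modularity(g, [set(b) for b in blocks])
            assert modularity(part, net) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# divisive loop and optimal cut

class TestNgDendrogram:
    def test_bridge_removed_first_and_split_into_triangles(self, two_triangles_bridge):
        dendro = ng_dendrogram(two_triangles_bridge, seed=0)
        assert dendro.removal_order[0] == ("c", "d")
        first_split, q = dendro.splits[0]
        assert sorted(map(sorted, first_split.communities())) == [
            ["a", "b", "c"],
            ["d", "e", "f"],
        ]
        assert q == pytest.approx(5 / 14)

    def test_single_edge_one_split(self):
        dendro = ng_dendrogram(make_net([("A", "B")]), seed=0)
        assert len(dendro.splits) == 1
        part, q = dendro.splits[0]
        assert part.k == 2 and q == pytest.approx(-0.5)

    def test_same_seed_same_removal_order(self, two_triangles_bridge):
        a = ng_dendrogram(two_triangles_bridge, seed=42)
        b = ng_dendrogram(two_triangles_bridge, seed=42)
        assert a.removal_order == b.removal_order
        assert [q for _, q in a.splits] == [q for _, q in b.splits]

    def test_component_counts_strictly_increase_to_singletons(self):
        g = nx.gnp_random_graph(10, 0.35, seed=2)
        g.remove_nodes_from(list(nx.isolates(g)))
        net = InteractionNetwork(graph=g, tau=0.8)
        dendro = ng_dendrogram(net, seed=1)
        ks = [p.k for p, _ in dendro.splits]
        assert ks == sorted(set(ks))
        assert dendro.splits[-1][0].k == g.number_of_nodes()  # all singletons

    def test_disconnected_input_records_initial_partition(self):
        net = make_net([("a", "b"), ("c", "d")])
        dendro = ng_dendrogram(net, seed=0)
        part, q = dendro.splits[0]
        assert part.k == 2
        assert sorted(map(sorted, part.communities())) == [["a", "b"], ["c", "d"]]
        assert q == pytest.approx(0.5)  # two disconnected dyads


class TestBestPartition:
    def test_two_triangles_bridge(self, two_triangles_bridge):
        cs = best_partition(ng_dendrogram(two_triangles_bridge, seed=0))
        assert cs.n_communities == 2
        assert cs.q_max == pytest.approx(5 / 14)
        assert sorted(map(sorted, cs.communities)) == [
            ["a", "b", "c"],
            ["d", "e", "f"],
        ]

    def test_tie_takes_earliest_split(self):
        parts = [
            Partition({"a": 0, "b": 0}, 1),
            Partition({"a": 0, "b": 1}, 2),
        ]
        dendro = Dendrogram(
            removal_order=[],
            splits=[(parts[0], 0.1), (parts[1], 0.3), (parts[0], 0.3), (parts[1], 0.2)],
            rng_seed=0,
        )
        cs = best_partition(dendro)
        assert cs.q_max == 0.3 and cs.partition is parts[1]

    def test_single_edge_graph(self):
        cs = best_partition(ng_dendrogram(make_net([("A", "B")]), seed=0))
        assert cs.q_max == pytest.approx(-0.5)
        assert cs.n_communities == 2


class TestPlantedPartitionRecovery:
    def test_recovers_planted_blocks(self):
        """4 blocks of 8, p_in=0.9, p_out=0.02: exact recovery in >=19/20 seeds."""
        from coexnet import evaluate_recovery

        hits = 0
        for seed in range(20):
            g = nx.planted_partition_graph(4, 8, 0.9, 0.02, seed=seed)
            g = nx.Graph(g)  # drop block metadata
            g.remove_nodes_from(list(nx.isolates(g)))
            net = InteractionNetwork(graph=g, tau=0.8)
            cs = best_partition(ng_dendrogram(net, seed=seed))
            truth = Partition.from_labels({v: v // 8 for v in g.nodes})
            if evaluate_recovery(cs.partition, truth) == 1.0:
                hits += 1
        assert hits >= 19
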