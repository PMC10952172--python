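import itertools
from collections import defaultdict

import numpy as np
import pytest

from cooccurnet.metrics import (
    DegenerateInputError,
    UndefinedStatisticError,
    betweenness,
    cv_edge_weights,
    density,
    modularity,
    walktrap,
)

from .conftest import network_from_weights, random_network


def brute_force_betweenness(net, mode="cost"):
    """Exhaustive simple-path enumeration oracle (feasible for <= 7 nodes)."""
    n = net.n_nodes
    w = net.weights
    cost = np.where(w > 0, w if mode == "cost" else np.divide(1.0, np.where(w > 0, w, 1)), np.inf)
    score = dict.fromkeys(net.nodes, 0.0)
    for s, t in itertools.combinations(range(n), 2):
        paths = []
        stack = [(s, (s,), 0.0)]
        while stack:
            v, path, c = stack.pop()
            if v == t:
                paths.append((c, path))
                continue
            for u in range(n):
                if np.isfinite(cost[v, u]) and u not in path:
                    stack.append((u, path + (u,), c + cost[v, u]))
        if not paths:
            continue
        best = min(c for c, _ in paths)
        shortest = [p for c, p in paths if c <= best + 1e-12]
        for p in shortest:
            for v in p[1:-1]:
                score[net.nodes[v]] += 1.0 / len(shortest)
    return score


def all_partitions(items):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [subset + [first]] + smaller[i + 1 :]
        yield smaller + [[first]]


def two_cliques_network():
    """Two disjoint 3-cliques with unit weights."""
    w = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for i, j in itertools.combinations(block, 2):
            w[i, j] = w[j, i] = 1.0
    return network_from_weights(w)


class TestDensity:
    def test_complete_graph(self):
        w = np.full((3, 3), 0.5)
        np.fill_diagonal(w, 0)
        assert density(network_from_weights(w)) == 1.0

    def test_partial(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 0.2
        w[2, 3] = w[3, 2] = 0.7
        assert density(network_from_weights(w)) == pytest.approx(0.2)

    def test_edgeless(self):
        assert density(network_from_weights(np.zeros((4, 4)))) == 0.0

    def test_single_node_degenerate(self):
        with pytest.raises(DegenerateInputError):
            density(network_from_weights(np.zeros((1, 1))))

    def test_invariant_to_rescaling(self):
        net = random_network(0)
        scaled = network_from_weights(net.weights * 0.5)
        assert density(net) == density(scaled)


class TestCvEdgeWeights:
    def test_constant_weights_give_zero(self):
        w = np.full((4, 4), 0.3)
        np.fill_diagonal(w, 0)
        assert cv_edge_weights(network_from_weights(w)) == 0.0

    def test_single_dyad_undefined(self):
        weights = np.array([[0, 0.2], [0.2, 0]])
        with pytest.raises(UndefinedStatisticError):
            cv_edge_weights(network_from_weights(weights))  # no sample SD of one value

    def test_two_dyads_value(self):
        # three nodes, dyad weights 0.2, 0.4, 0.6: mean .4, sd .2 -> CV = .5
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.2
        w[0, 2] = w[2, 0] = 0.4
        w[1, 2] = w[2, 1] = 0.6
        assert cv_edge_weights(network_from_weights(w)) == pytest.approx(0.5)

    def test_matches_direct_recomputation(self):
        net = random_network(1)
        v = net.upper_triangle()
        assert cv_edge_weights(net) == pytest.approx(v.std(ddof=1) / v.mean(), abs=1e-12)

    def test_scale_invariant(self):
        net = random_network(2)
        scaled = network_from_weights(net.weights * 0.25)
        assert cv_edge_weights(net) == pytest.approx(cv_edge_weights(scaled), abs=1e-12)

    def test_nonzero_dyads_option(self):
        net = random_network(3)
        v = net.upper_triangle()
        nz = v[v > 0]
        assert cv_edge_weights(net, include_zero_dyads=False) == pytest.approx(
            nz.std(ddof=1) / nz.mean()
        )

    def test_all_zero_mean_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cv_edge_weights(network_from_weights(np.zeros((4, 4))))


class TestBetweenness:
    def test_path_graph(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        scores = betweenness(network_from_weights(w))
        assert scores == {"n0": 0.0, "n1": 1.0, "n2": 0.0}

    def test_star_graph(self):
        w = np.zeros((5, 5))
        for leaf in range(1, 5):
            w[0, leaf] = w[leaf, 0] = 0.3
        scores = betweenness(network_from_weights(w))
        assert scores["n0"] == 6.0  # all C(4,2) leaf pairs route through the hub
        assert all(scores[f"n{i}"] == 0.0 for i in range(1, 5))

    def test_tied_paths_share_credit(self):
        # s-t connected via v and w with equal total cost: each gets 1/2
        w = np.zeros((4, 4))
        for a, b in [(0, 1), (1, 3), (0, 2), (2, 3)]:
            w[a, b] = w[b, a] = 0.25
        scores = betweenness(network_from_weights(w))
        assert scores["n1"] == pytest.approx(0.5)
        assert scores["n2"] == pytest.approx(0.5)

    @pytest.mark.parametrize("mode", ["cost", "similarity_reciprocal"])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed, mode):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        w = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        # power-of-two weights keep both the weights and their reciprocals
        # exactly representable, so path-cost ties are exact in float
        vals = 1.0 / 2 ** rng.integers(0, 4, size=len(iu[0]))
        mask = rng.random(len(iu[0])) < 0.5
        w[iu] = np.where(mask, vals, 0.0)
        w += w.T
        net = network_from_weights(w)
        ours = betweenness(net, weight_mode=mode)
        oracle = brute_force_betweenness(net, mode=mode)
        for node in net.nodes:
            assert ours[node] == pytest.approx(oracle[node], abs=1e-9)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            betweenness(random_network(0), weight_mode="similarity")


class TestModularity:
    def test_single_module_is_zero(self):
        net = random_network(4)
        assert modularity(net, dict.fromkeys(net.nodes, 0)) == pytest.approx(0.0)

    def test_two_cliques_split(self):
        net = two_cliques_network()
        part = {n: (0 if i < 3 else 1) for i, n in enumerate(net.nodes)}
        assert modularity(net, part) == pytest.approx(0.5)

    def test_bounds_on_random_partitions(self):
        net = random_network(5)
        rng = np.random.default_rng(0)
        for _ in range(20):
            part = {n: int(rng.integers(0, 4)) for n in net.nodes}
            assert -0.5 <= modularity(net, part) <= 1.0

    def test_matches_networkx(self):
        import networkx as nx

        net = random_network(6)
        part = {n: i % 3 for i, n in enumerate(net.nodes)}
        g = net.to_networkx()
        groups = defaultdict(set)
        for node, mod in part.items():
            groups[mod].add(node)
        expected = nx.community.modularity(g, groups.values(), weight="weight")
        assert modularity(net, part) == pytest.approx(expected, abs=1e-12)

    def test_incomplete_partition_rejected(self):
        net = random_network(7)
        with pytest.raises(ValueError):
            modularity(net, {net.nodes[0]: 0})


class TestWalktrap:
    def test_two_cliques_recovered_with_exhaustive_maximum(self):
        net = two_cliques_network()
        part = walktrap(net)
        modules = {frozenset(m) for m in part.modules()}
        assert modules == {frozenset(net.nodes[:3]), frozenset(net.nodes[3:])}
        # exhaustive search over all 203 partitions of 6 nodes confirms the optimum
        best = max(
            modularity(net, {n: i for i, block in enumerate(p) for n in block})
            for p in all_partitions(net.nodes)
        )
        assert part.modularity == pytest.approx(best) == pytest.approx(0.5)

    def test_single_clique_is_one_module(self):
        w = np.ones((4, 4)) * 0.6
        np.fill_diagonal(w, 0)
        part = walktrap(network_from_weights(w))
        assert part.n_modules == 1
        assert part.modularity == pytest.approx(0.0)

    def test_never_worse_than_trivial_partition(self):
        for seed in range(8):
            net = random_network(seed, n=15, p_edge=0.25)
            assert walktrap(net).modularity >= -1e-12  # all-in-one scores 0

    def test_isolated_nodes_stay_singletons(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        part = walktrap(network_from_weights(w))
        assert part.assignment["n2"] != part.assignment["n3"]

    def test_every_node_assigned_once(self):
        net = random_network(9, n=20, p_edge=0.2)
        part = walktrap(net)
        assert set(part.assignment) == set(net.nodes)
        assert part.n_modules == len(set(part.assignment.values()))

    def test_agrees_with_igraph_on_benchmark_graphs(self):
        """Planted three-community benchmarks: partitions match the reference
        implementation (label-permutation invariant) on >= 95% of graphs."""
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(0)

        def canon(assignment):
            groups = defaultdict(set)
            for node, mod in assignment.items():
                groups[mod].add(node)
            return frozenset(frozenset(s) for s in groups.values())

        agree = 0
        n_graphs = 20
        for _ in range(n_graphs):
            n, k = 30, 3
            labels = np.repeat(np.arange(k), n // k)
            w = np.zeros((n, n))
            for i, j in itertools.combinations(range(n), 2):
                p = 0.8 if labels[i] == labels[j] else 0.02
                if rng.random() < p:
                    w[i, j] = w[j, i] = 0.5 + 0.5 * rng.random()
            net = network_from_weights(w)
            part = walktrap(net, steps=4)
            g = igraph.Graph.Weighted_Adjacency(
                w.tolist(), mode="undirected", attr="weight", loops=False
            )
            cl = g.community_walktrap(weights="weight", steps=4).as_clustering()
            ref = {net.nodes[i]: cl.membership[i] for i in range(n)}
            agree += canon(part.assignment) == canon(ref)
        assert agree >= 0.95 * n_graphs
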