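"""Bipartite/unipartite network construction, centralities and hubs.

Brute-force oracles used here: shared-partner counts by explicit set
intersection, connected components by union-find, betweenness by exhaustive
shortest-path enumeration (depth-limited DFS), harmonic closeness from a
BFS distance matrix, and the eigenvector by dense symmetric
eigendecomposition per component.
"""
import itertools

import networkx as nx
import numpy as np
import pytest

from mirnet import (
    CorrelationEdge,
    CorrelationEdgeSet,
    ValidationError,
    build_bipartite,
    centralities,
    filter_core,
    find_hubs,
    mirna_degree,
    project_unipartite,
    summarize_network,
)


def edge_set(pairs, rho=-0.5, n=30):
    return CorrelationEdgeSet(
        edges=[CorrelationEdge(m, g, rho, n) for m, g in pairs], rho_max=-0.4
    )


def random_bipartite_pairs(rng, n_mirna=4, n_mrna=6, p=0.4):
    pairs = []
    for i in range(n_mirna):
        for j in range(n_mrna):
            if rng.random() < p:
                pairs.append((f"m{i}", f"g{j}"))
    return pairs


# ---------------------------------------------------------------- oracles


def oracle_projection_weight(pairs, a, b):
    na = {g for m, g in pairs if m == a}
    nb = {g for m, g in pairs if m == b}
    return len(na & nb)


def oracle_components_union_find(nodes, edges):
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        parent[find(u)] = find(v)
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return {frozenset(g) for g in groups.values()}


def oracle_betweenness(graph):
    """Split-credit betweenness by exhaustive enumeration of shortest paths."""
    nodes = sorted(graph.nodes)
    scores = {n: 0.0 for n in nodes}
    lengths = dict(nx.all_pairs_shortest_path_length(graph))
    for s, t in itertools.combinations(nodes, 2):
        if t not in lengths[s]:
            continue
        d = lengths[s][t]
        paths = []

        def extend(path):
            last = path[-1]
            if last == t:
                paths.append(list(path))
                return
            if len(path) - 1 >= d:
                return
            for nbr in graph.neighbors(last):
                # only steps that can still reach t within distance d
                if nbr not in path and lengths[s].get(nbr) == len(path) and \
                        lengths[nbr].get(t, d + 1) == d - len(path):
                    path.append(nbr)
                    extend(path)
                    path.pop()

        extend([s])
        for p in paths:
            for interior in p[1:-1]:
                scores[interior] += 1.0 / len(paths)
    return scores


def oracle_harmonic_closeness(graph):
    nodes = sorted(graph.nodes)
    lengths = dict(nx.all_pairs_shortest_path_length(graph))
    return {
        n: sum(1.0 / d for m, d in lengths[n].items() if m != n) for n in nodes
    }


def oracle_eigenvector(graph):
    """Dense eigendecomposition per component; same winner rule as the engine."""
    nodes = sorted(graph.nodes)
    comps = [sorted(c) for c in nx.connected_components(graph)]
    if graph.number_of_edges() == 0:
        return {n: 1.0 for n in nodes}
    candidates = []
    for comp in comps:
        a = nx.to_numpy_array(graph, nodelist=comp, weight="weight")
        if len(comp) == 1 or a.max() == 0:
            lam, vec = 0.0, np.ones(len(comp))
        else:
            w, v = np.linalg.eigh(a)
            lam = float(w[-1])
            vec = np.abs(v[:, -1])
        candidates.append((round(lam, 9), len(comp), comp[0], comp, vec))
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
    _, _, _, comp, vec = candidates[0]
    scores = {n: 0.0 for n in nodes}
    for n, v in zip(comp, vec / vec.max()):
        scores[n] = float(v)
    return scores


# ------------------------------------------------------------------ tests


class TestBuildBipartite:
    def test_small_example_counts(self):
        net = build_bipartite(edge_set([("A", "g1"), ("A", "g2"), ("B", "g2")]))
        assert net.mirna_nodes == {"A", "B"}
        assert net.mrna_nodes == {"g1", "g2"}
        assert net.n_edges == 3

    def test_empty_edge_set(self):
        net = build_bipartite(CorrelationEdgeSet(edges=[], rho_max=-0.4))
        assert net.n_edges == 0 and not net.mirna_nodes

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            CorrelationEdgeSet(
                edges=[
                    CorrelationEdge("A", "g1", -0.5, 10),
                    CorrelationEdge("A", "g1", -0.6, 10),
                ],
                rho_max=-0.4,
            )

    def test_degree_sum_equals_edge_count(self, rng):
        pairs = list(
            {
                (f"m{rng.integers(0, 20)}", f"g{rng.integers(0, 50)}")
                for _ in range(200)
            }
        )
        net = build_bipartite(edge_set(pairs))
        assert sum(mirna_degree(net).values()) == net.n_edges == len(pairs)


class TestFilterCore:
    def _star_net(self):
        pairs = (
            [("m1", f"g{i}") for i in range(25)]
            + [("m2", f"g{i}") for i in range(20)]
            + [("m3", f"g{i}") for i in range(5)]
        )
        return build_bipartite(edge_set(pairs))

    def test_strict_inequality_default(self):
        core = filter_core(self._star_net(), min_degree=20)
        assert core.mirna_nodes == {"m1"}

    def test_keep_equal_flag(self):
        core = filter_core(self._star_net(), min_degree=20, keep_equal=True)
        assert core.mirna_nodes == {"m1", "m2"}

    def test_min_degree_zero_is_identity(self):
        net = self._star_net()
        core = filter_core(net, min_degree=0)
        assert core.mirna_nodes == net.mirna_nodes
        assert core.n_edges == net.n_edges

    def test_retained_edges_match_retained_degrees(self, rng):
        pairs = random_bipartite_pairs(rng, n_mirna=8, n_mrna=15, p=0.35)
        net = build_bipartite(edge_set(pairs))
        degrees = mirna_degree(net)
        core = filter_core(net, min_degree=4)
        assert core.n_edges == sum(d for m, d in degrees.items() if d > 4)
        # dangling mRNAs dropped
        assert all(core.graph.degree[g] > 0 for g in core.mrna_nodes)


class TestProjection:
    def test_single_shared_partner(self):
        net = build_bipartite(
            edge_set([("A", "g1"), ("A", "g2"), ("B", "g2"), ("B", "g3")])
        )
        proj = project_unipartite(net)
        assert proj.weight("A", "B") == 1

    def test_disjoint_targets_stay_isolated(self):
        net = build_bipartite(
            edge_set([("A", "g1"), ("A", "g2"), ("B", "g3"), ("B", "g4")])
        )
        proj = project_unipartite(net)
        assert proj.weight("A", "B") == 0
        assert proj.nodes == {"A", "B"}

    def test_weights_match_set_intersection_oracle(self, rng):
        for _ in range(20):
            pairs = random_bipartite_pairs(rng, n_mirna=5, n_mrna=8, p=0.4)
            if not pairs:
                continue
            net = build_bipartite(edge_set(pairs))
            proj = project_unipartite(net)
            mirnas = sorted(net.mirna_nodes)
            for a, b in itertools.combinations(mirnas, 2):
                assert proj.weight(a, b) == oracle_projection_weight(pairs, a, b)

    def test_weight_bounded_by_min_degree(self, rng):
        pairs = random_bipartite_pairs(rng, n_mirna=6, n_mrna=10, p=0.5)
        net = build_bipartite(edge_set(pairs))
        proj = project_unipartite(net)
        deg = mirna_degree(net)
        for a, b, data in proj.graph.edges(data=True):
            assert 1 <= data["weight"] <= min(deg[a], deg[b])


class TestCentralities:
    def _table(self, proj_pairs, weights=None):
        g = nx.Graph()
        for i, (a, b) in enumerate(proj_pairs):
            g.add_edge(a, b, weight=1 if weights is None else weights[i])
        from mirnet.network import UnipartiteProjection

        proj = UnipartiteProjection(graph=g)
        degrees = {n: 1 for n in g.nodes}
        return centralities(proj, degrees)

    def test_path_betweenness(self):
        t = self._table([("A", "B"), ("B", "C")])
        assert t.loc["B", "betweenness"] == pytest.approx(1.0)
        assert t.loc["A", "betweenness"] == t.loc["C", "betweenness"] == 0.0

    def test_square_half_integer_betweenness(self):
        # two equally short paths between opposite corners: credit splits
        t = self._table([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        assert np.allclose(t["betweenness"], 0.5)

    def test_triangle_equal_eigenvector(self):
        t = self._table([("A", "B"), ("B", "C"), ("C", "A")])
        assert np.allclose(t["eigenvector"], 1.0)

    def test_harmonic_closeness_path(self):
        t = self._table([("A", "B"), ("B", "C")])
        assert t.loc["A", "closeness"] == pytest.approx(1.0 + 0.5)
        assert t.loc["B", "closeness"] == pytest.approx(2.0)

    def test_eigenvector_satisfies_eigen_equation(self, rng):
        pairs = random_bipartite_pairs(rng, n_mirna=6, n_mrna=9, p=0.45)
        net = build_bipartite(edge_set(pairs))
        proj = project_unipartite(net)
        if proj.graph.number_of_edges() == 0:
            pytest.skip("degenerate draw")
        t = centralities(proj, mirna_degree(net))
        nodes = sorted(proj.graph.nodes)
        a = nx.to_numpy_array(proj.graph, nodelist=nodes, weight="weight")
        v = t.loc[nodes, "eigenvector"].to_numpy()
        support = v > 0
        if support.sum() > 1:
            av = a @ v
            lam = av[support] @ v[support] / (v[support] @ v[support])
            assert np.linalg.norm(av[support] - lam * v[support]) <= 1e-8 * max(lam, 1.0)
        assert v.max() == pytest.approx(1.0)

    def test_empty_projection_gives_empty_table(self):
        from mirnet.network import UnipartiteProjection

        t = centralities(UnipartiteProjection(graph=nx.Graph()), {})
        assert len(t) == 0

    def test_degree_column_repeats_bipartite_degree(self, rng):
        pairs = random_bipartite_pairs(rng, n_mirna=5, n_mrna=12, p=0.5)
        net = build_bipartite(edge_set(pairs))
        t = centralities(project_unipartite(net), mirna_degree(net))
        for m, d in mirna_degree(net).items():
            assert t.loc[m, "degree"] == d


class TestFindHubs:
    def test_component_partition(self):
        net = build_bipartite(edge_set([("A", "g1"), ("B", "g1"), ("C", "g2")]))
        hubs = find_hubs(net)
        assert [h.member_mirnas for h in hubs] == [
            frozenset({"A", "B"}),
            frozenset({"C"}),
        ]
        assert [h.edge_count for h in hubs] == [2, 1]
        assert sum(h.edge_fraction for h in hubs) == pytest.approx(1.0)

    def test_fully_connected_single_hub(self):
        pairs = [(m, g) for m in "AB" for g in ("g1", "g2")]
        hubs = find_hubs(build_bipartite(edge_set(pairs)))
        assert len(hubs) == 1 and hubs[0].edge_fraction == pytest.approx(1.0)

    def test_partition_invariant_to_edge_order_and_matches_union_find(self, rng):
        pairs = random_bipartite_pairs(rng, n_mirna=7, n_mrna=10, p=0.25)
        if not pairs:
            pytest.skip("degenerate draw")
        net1 = build_bipartite(edge_set(pairs))
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        net2 = build_bipartite(edge_set(shuffled))
        parts1 = {h.member_mirnas for h in find_hubs(net1)}
        parts2 = {h.member_mirnas for h in find_hubs(net2)}
        assert parts1 == parts2
        nodes = set(itertools.chain.from_iterable(pairs))
        oracle = oracle_components_union_find(nodes, pairs)
        oracle_mirna_parts = {
            frozenset(n for n in comp if n.startswith("m")) for comp in oracle
        }
        oracle_mirna_parts.discard(frozenset())
        assert parts1 == oracle_mirna_parts


class TestSummarize:
    def test_counts_and_share(self):
        pairs = [("A", f"g{i}") for i in range(8)] + [("B", "g0")]
        net = build_bipartite(edge_set(pairs))
        core = filter_core(net, min_degree=5)
        hubs = find_hubs(core)
        table = centralities(project_unipartite(core), mirna_degree(net))
        s = summarize_network(net, core, hubs, table)
        assert s["total_edges"] == 9
        assert s["core_mirna_count"] == 1
        assert s["core_edge_share_pct"] == round(100 * 8 / 9)
        assert sum(h["edge_fraction"] for h in s["hubs"]) == pytest.approx(1.0)

    def test_single_edge_network_extremes(self):
        net = build_bipartite(edge_set([("A", "g1")]))
        core0 = filter_core(net, min_degree=0)
        s0 = summarize_network(net, core0, find_hubs(core0),
                               centralities(project_unipartite(core0), mirna_degree(net)))
        assert s0["core_edge_share_pct"] == 100
        core5 = filter_core(net, min_degree=5)
        s5 = summarize_network(net, core5, find_hubs(core5),
                               centralities(project_unipartite(core5), mirna_degree(net)))
        assert s5["core_edge_share_pct"] == 0
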