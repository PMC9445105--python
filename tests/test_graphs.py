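"""Graph generators, statistics, subgraph sampling, and hashing."""

import math

import networkx as nx
import numpy as np
import pytest

from l2psync.graphs import (
    Graph,
    NwsParams,
    expected_edge_count,
    generate_nws_plus,
    graph_features,
    load_edgelist,
    make_topology,
    sample_connected_induced_subgraph,
    save_edgelist,
    wl_hash,
)


@pytest.mark.parametrize(
    "kind,n,checks",
    [
        ("complete", 30, {"num_edges": 435, "diameter": 1}),
        ("ring", 30, {"num_edges": 30, "diameter": 15, "min_degree": 2, "max_degree": 2}),
        ("path", 30, {"num_edges": 29, "diameter": 29, "min_degree": 1, "max_degree": 2}),
    ],
)
def test_special_topologies(kind, n, checks):
    f = graph_features(make_topology(kind, n))
    for key, val in checks.items():
        assert getattr(f, key) == val


def test_random_tree_bounded_degree(rng):
    for _ in range(10):
        t = make_topology("random_tree", 30, max_degree=4, rng=rng)
        assert t.num_edges == 29
        assert t.is_connected()
        assert t.degrees().max() <= 4


def test_make_topology_errors():
    with pytest.raises(ValueError):
        make_topology("torus", 10)
    with pytest.raises(ValueError):
        make_topology("ring", 2)
    with pytest.raises(ValueError):
        make_topology("random_tree", 10, max_degree=1)


def test_nws_params_validation():
    with pytest.raises(ValueError):
        NwsParams(10, 3, 0.5, 1)  # odd k
    with pytest.raises(ValueError):
        NwsParams(10, 2, 0.5, 0)  # M < 1
    with pytest.raises(ValueError):
        NwsParams(10, 2, 8.0, 1)  # per-round probability > 1


def test_nws_zero_p_is_ring_lattice(rng):
    g = generate_nws_plus(NwsParams(30, 2, 0.0, 1), rng)
    assert g.edge_list() == make_topology("ring", 30).edge_list()
    g4 = generate_nws_plus(NwsParams(10, 4, 0.0, 1), rng)
    assert g4.degrees().tolist() == [4] * 10


def test_nws_unit_probability_gives_complete_graph(rng):
    # p/(n-k-1) = 1 adds every non-edge: the limiting case is complete
    g = generate_nws_plus(NwsParams(15, 2, 12.0, 1), rng)
    assert g.num_edges == 15 * 14 // 2


def test_nws_contains_ring_lattice(rng):
    lattice = set(make_topology("ring", 30).edge_list())
    for _ in range(20):
        g = generate_nws_plus(NwsParams(30, 2, 0.65, 1), rng)
        assert lattice <= set(g.edge_list())
        assert g.is_connected()


def test_expected_edge_count_closed_forms():
    p = NwsParams(30, 2, 0.65, 1)
    # leading order: nk/2 + n^2 p M / (2(n-k-1))
    assert expected_edge_count(p, "leading") == pytest.approx(30 + 900 * 0.65 / 54)
    exact = 30 + (math.comb(30, 2) - 30) * (0.65 / 27)
    assert expected_edge_count(p, "exact") == pytest.approx(exact)
    assert expected_edge_count(NwsParams(30, 2, 0.0, 3), "exact") == 30.0
    p2 = NwsParams(30, 2, 0.85, 1)
    assert expected_edge_count(p2, "leading") == pytest.approx(30 + 900 * 0.85 / 54)


def test_graph_features_matches_bruteforce_bfs(rng):
    """Diameter agrees with an all-pairs BFS oracle on random small graphs."""
    checked = 0
    while checked < 100:
        n = int(rng.integers(4, 9))
        gnx = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
        if not nx.is_connected(gnx):
            continue
        G = Graph.from_edges(n, gnx.edges())
        # oracle: explicit BFS from every node
        dia = 0
        for s in range(n):
            dist = {s: 0}
            frontier = [s]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in gnx.neighbors(u):
                        if v not in dist:
                            dist[v] = dist[u] + 1
                            nxt.append(v)
                frontier = nxt
            dia = max(dia, max(dist.values()))
        f = graph_features(G)
        assert f.diameter == dia
        assert f.num_edges == gnx.number_of_edges()
        assert f.min_degree == min(d for _, d in gnx.degree())
        assert f.max_degree == max(d for _, d in gnx.degree())
        checked += 1


def test_graph_features_disconnected_raises():
    G = Graph.from_edges(4, [(0, 1), (2, 3)])
    with pytest.raises(ValueError, match="disconnected"):
        graph_features(G)


def test_subgraph_sampling_connected(rng):
    g = generate_nws_plus(NwsParams(60, 2, 0.4, 1), rng)
    for n0 in (2, 10, 30, 60):
        nodes = sample_connected_induced_subgraph(g, n0, rng)
        assert len(set(nodes)) == n0
        sub = g.induced_subgraph(nodes)
        assert sub.is_connected()
    assert sorted(sample_connected_induced_subgraph(g, 60, rng)) == list(range(60))
    with pytest.raises(ValueError):
        sample_connected_induced_subgraph(g, 61, rng)


def test_subgraph_of_ring_is_arc(rng):
    """Connected induced subgraphs of a cycle are exactly its arcs (paths)."""
    ring = make_topology("ring", 600)
    nodes = sample_connected_induced_subgraph(ring, 30, rng)
    sub = ring.induced_subgraph(nodes)
    f = graph_features(sub)
    assert f.num_edges == 29 and f.max_degree == 2 and f.min_degree == 1


def test_wl_hash_isomorphism_invariance(rng):
    t = make_topology("random_tree", 20, max_degree=5, rng=rng)
    perm = rng.permutation(20)
    relabeled = Graph.from_edges(20, [(perm[u], perm[v]) for u, v in t.edge_list()])
    assert wl_hash(t) == wl_hash(relabeled)
    assert wl_hash(t) == wl_hash(t)  # deterministic
    assert wl_hash(make_topology("ring", 30)) != wl_hash(make_topology("path", 30))


def test_edgelist_round_trip(tmp_path, rng):
    g = generate_nws_plus(NwsParams(15, 2, 0.65, 1), rng)
    path = tmp_path / "g.edgelist"
    save_edgelist(g, path)
    g2 = load_edgelist(path)
    assert g2.num_nodes == g.num_nodes and g2.edges == g.edges
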