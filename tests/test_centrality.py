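"""Centrality measures against closed forms and exhaustive oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fanet.centrality import (
    MEASURES,
    betweenness_centrality,
    centrality_report,
    classify_strength,
    closeness_centrality,
    degree_centrality,
    eigenvector_centrality,
    hypergraph_centrality,
)
from fanet.netbuild import Hypergraph, build_graph, build_hypergraph

from conftest import random_association


def star(k=3):
    g = nx.star_graph(k)  # node 0 is the center
    return g


# --- independent oracles -------------------------------------------------


def bfs_distances(g, source):
    """Plain breadth-first distances, independent of networkx shortest paths."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def closeness_oracle(g):
    """Wasserman-Faust closeness from raw BFS distances."""
    n = g.number_of_nodes()
    out = {}
    for v in g.nodes:
        dist = bfs_distances(g, v)
        reach = len(dist) - 1
        if reach == 0:
            out[v] = np.nan
            continue
        out[v] = (reach / (n - 1)) * (reach / sum(dist.values()))
    return pd.Series(out, dtype=float)


def all_simple_paths(g, s, t):
    """Exhaustive DFS enumeration of simple s-t paths."""
    paths = []

    def walk(node, seen, path):
        if node == t:
            paths.append(tuple(path))
            return
        for nbr in g.neighbors(node):
            if nbr not in seen:
                walk(nbr, seen | {nbr}, path + [nbr])

    walk(s, {s}, [s])
    return paths


def betweenness_oracle(g):
    """Betweenness by exhaustive shortest-path enumeration (n <= 7)."""
    nodes = list(g.nodes)
    n = len(nodes)
    raw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = all_simple_paths(g, s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sps = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in sps if v in p)
            raw[v] += through / len(sps)
    norm = (n - 1) * (n - 2) / 2 or 1.0
    return pd.Series({v: raw[v] / norm for v in nodes}, dtype=float)


# --- closed-form examples ------------------------------------------------


def test_degree_star_and_complete():
    s = degree_centrality(star(3))
    assert s[0] == 1.0 and all(s[i] == pytest.approx(1 / 3) for i in (1, 2, 3))
    k4 = degree_centrality(nx.complete_graph(4))
    assert (k4 == 1.0).all()
    g = nx.empty_graph(3)
    assert (degree_centrality(g) == 0.0).all()


def test_closeness_path_star_isolated():
    path = nx.path_graph(3)  # 0-1-2
    cc = closeness_centrality(path)
    assert cc[1] == pytest.approx(1.0)
    assert cc[0] == pytest.approx(2 / 3)
    st = closeness_centrality(star(3))
    assert st[0] == pytest.approx(1.0)
    assert st[1] == pytest.approx(0.6)  # 3 / (1 + 2 + 2)
    g = nx.Graph()
    g.add_nodes_from(["a", "b", "c"])
    g.add_edge("a", "b")
    assert np.isnan(closeness_centrality(g)["c"])


def test_betweenness_star_k4_path():
    bc = betweenness_centrality(star(3))
    assert bc[0] == pytest.approx(1.0) and bc[1] == 0.0
    assert (betweenness_centrality(nx.complete_graph(4)) == 0.0).all()
    assert betweenness_centrality(nx.path_graph(3))[1] == pytest.approx(1.0)


def test_eigenvector_k4_star_disconnected():
    ec = eigenvector_centrality(nx.complete_graph(4))
    assert np.allclose(ec, 0.5)
    st = eigenvector_centrality(star(3))
    assert st[0] == pytest.approx(1 / np.sqrt(2), abs=1e-8)
    assert st[1] == pytest.approx(1 / np.sqrt(6), abs=1e-8)
    # dominant component carries the mass: triangle + lone edge
    g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4)])
    ec = eigenvector_centrality(g)
    assert ec[0] > 0.5 and ec[3] < 1e-6


def test_eigenvector_edgeless_warns_zero():
    with pytest.warns(UserWarning):
        ec = eigenvector_centrality(nx.empty_graph(3))
    assert (ec == 0.0).all()


def test_eigenvector_fixed_point(rng):
    for _ in range(20):
        g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(2**31)))
        if g.number_of_edges() == 0:
            continue
        e = eigenvector_centrality(g).to_numpy()
        a = nx.to_numpy_array(g)
        lam = e @ a @ e
        assert np.linalg.norm(a @ e - lam * e) < 1e-8
        assert e.min() >= 0 and np.linalg.norm(e) == pytest.approx(1.0)


def test_eigenvector_matches_networkx_oracle(rng):
    for _ in range(20):
        g = nx.gnp_random_graph(7, 0.5, seed=int(rng.integers(2**31)))
        if g.number_of_edges() == 0 or not nx.is_connected(g):
            continue
        mine = eigenvector_centrality(g)
        ref = pd.Series(nx.eigenvector_centrality_numpy(g)).abs()
        assert np.allclose(mine, ref / np.linalg.norm(ref), atol=1e-7)


def test_oracle_equivalence_all_graphs_up_to_6_nodes():
    """Betweenness and closeness agree with exhaustive-enumeration oracles
    on every graph with at most 6 nodes (atlas enumeration)."""
    atlas = nx.graph_atlas_g()
    small = [g for g in atlas[1:] if 2 <= g.number_of_nodes() <= 6]
    assert len(small) > 200
    for g in small:
        bc, bco = betweenness_centrality(g), betweenness_oracle(g)
        assert np.allclose(bc, bco, atol=1e-12), nx.to_dict_of_lists(g)
        cc, cco = closeness_centrality(g), closeness_oracle(g)
        assert np.allclose(cc, cco, atol=1e-12, equal_nan=True)


def test_permutation_equivariance(rng):
    g = nx.gnp_random_graph(8, 0.4, seed=5)
    mapping = dict(zip(g.nodes, rng.permutation(list(g.nodes))))
    h = nx.relabel_nodes(g, mapping)
    for fn in (degree_centrality, closeness_centrality, betweenness_centrality,
               eigenvector_centrality):
        a, b = fn(g), fn(h)
        for v in g.nodes:
            x, y = a[v], b[mapping[v]]
            assert (np.isnan(x) and np.isnan(y)) or x == pytest.approx(y, abs=1e-9)


# --- hypergraph centralities ---------------------------------------------


def test_single_hyperedge_is_k3():
    h = Hypergraph(("A", "B", "C"), (("e1", frozenset({"A", "B", "C"})),))
    dc = hypergraph_centrality(h, "degree")
    assert (dc == 1.0).all()


def test_two_section_degree_matches_graph(rng):
    for _ in range(10):
        m = random_association(rng, 7)
        g = build_graph(m, 0.4)
        h = build_hypergraph(m, 0.4, "maximal_clique")
        assert hypergraph_centrality(h, "degree").equals(degree_centrality(g))


def test_empty_hypergraph_all_zero_degree():
    h = Hypergraph(("A", "B", "C"), ())
    assert (hypergraph_centrality(h, "degree") == 0.0).all()


def test_bipartite_variant_restricts_to_nodes():
    h = Hypergraph(("A", "B", "C"), (("e1", frozenset({"A", "B"})),
                                     ("e2", frozenset({"B", "C"}))))
    s = hypergraph_centrality(h, "degree", representation="bipartite")
    assert list(s.index) == ["A", "B", "C"]
    assert s["B"] > s["A"]


def test_unknown_measure_rejected():
    h = Hypergraph(("A", "B"), (("e1", frozenset({"A", "B"})),))
    with pytest.raises(ValueError):
        hypergraph_centrality(h, "pagerank")


# --- strength bands -------------------------------------------------------


@pytest.mark.parametrize(
    "value,label",
    [(0.0, "weak"), (0.3, "weak"), (0.35, "moderate"), (0.4, "moderate"),
     (0.5, "moderate"), (0.6, "moderate"), (0.65, "moderate"),
     (0.7, "strong"), (1.0, "strong")],
)
def test_classify_strength_bands(value, label):
    assert classify_strength(value) == label


def test_classify_strength_rejects_out_of_range_and_passes_nan():
    with pytest.raises(ValueError):
        classify_strength(1.2)
    with pytest.raises(ValueError):
        classify_strength(-0.1)
    assert classify_strength(float("nan")) is None


def test_centrality_report_layout():
    g = nx.path_graph(4)
    rep = centrality_report(g)
    assert list(rep.columns[:4]) == list(MEASURES)
    assert {f"{m}_strength" for m in MEASURES} <= set(rep.columns)
    assert len(rep) == 4
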