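"""Node centrality measures and strength classification.

Four measures are computed per node, all normalized to [0, 1]:

* degree centrality: k_i / (n - 1), the fraction of possible direct links;
* closeness centrality: within-component closeness with Wasserman-Faust
  component-size scaling; undefined (NaN) for isolated nodes;
* betweenness centrality: shortest-path betweenness, endpoints excluded,
  normalized by (n-1)(n-2)/2;
* eigenvector centrality: the principal eigenvector of the unweighted
  adjacency matrix, unit Euclidean norm, nonnegative.

Values are classified as weak (<= 0.3), moderate, or strong (>= 0.7); the
published banding leaves (0.3, 0.4) and (0.6, 0.7) unassigned and these are
completed to the nearest band, i.e. moderate.

Hypergraph centralities are computed on the two-section (clique-expansion)
graph by default; a bipartite variant runs the measure on the
node-hyperedge incidence graph and restricts it back to the variable nodes.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import Hypergraph

__all__ = [
    "MEASURES",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "hypergraph_centrality",
    "classify_strength",
    "centrality_report",
]

MEASURES = ("degree", "betweenness", "eigenvector", "closeness")


def _as_series(d: Mapping, g: nx.Graph) -> pd.Series:
    return pd.Series({v: d[v] for v in g.nodes}, dtype=float)


def degree_centrality(g: nx.Graph) -> pd.Series:
    """Fraction of the other n-1 nodes directly connected to each node."""
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    return _as_series(nx.degree_centrality(g), g)


def closeness_centrality(g: nx.Graph) -> pd.Series:
    """Wasserman-Faust closeness; isolated nodes are undefined (NaN)."""
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    cc = nx.closeness_centrality(g, wf_improved=True)
    s = _as_series(cc, g)
    isolated = [v for v in g.nodes if g.degree(v) == 0]
    s[isolated] = np.nan
    return s


def betweenness_centrality(g: nx.Graph) -> pd.Series:
    """Shortest-path betweenness, endpoints excluded, pair-normalized."""
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    return _as_series(nx.betweenness_centrality(g, normalized=True), g)


def eigenvector_centrality(
    g: nx.Graph, tol: float = 1e-10, max_iter: int = 1000
) -> pd.Series:
    """Principal adjacency eigenvector by power iteration.

    Iterates on A + I from a uniform start (the identity shift leaves the
    eigenvectors unchanged while making the iteration converge on bipartite
    graphs), renormalizing to unit Euclidean norm each step, until the
    iterate moves by less than ``tol`` (max-abs) or ``max_iter`` is hit.
    An edgeless graph yields the all-zero vector with a warning.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    if g.number_of_edges() == 0:
        warnings.warn("graph has no edges; eigenvector centrality is all-zero")
        return pd.Series(0.0, index=nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        nxt = a @ x + x
        nxt /= np.linalg.norm(nxt)
        if np.abs(nxt - x).max() < tol:
            x = nxt
            break
        x = nxt
    x = np.abs(x)  # nonnegative by Perron-Frobenius; clear numerical -0
    return pd.Series(x, index=nodes)


_MEASURE_FUNCS = {
    "degree": degree_centrality,
    "closeness": closeness_centrality,
    "betweenness": betweenness_centrality,
    "eigenvector": eigenvector_centrality,
}


def hypergraph_centrality(
    h: Hypergraph, measure: str, representation: str = "two_section"
) -> pd.Series:
    """Centrality of a hypergraph's nodes.

    ``two_section`` (default) runs the measure on the clique-expansion
    graph.  ``bipartite`` runs it on the node-hyperedge incidence graph and
    restricts the result to the variable nodes (hyperedge vertices are
    dropped from the output but participate in paths and normalization).
    """
    if measure not in _MEASURE_FUNCS:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if representation == "two_section":
        g = h.two_section()
        return _MEASURE_FUNCS[measure](g)
    if representation == "bipartite":
        g = h.incidence_bipartite()
        if g.number_of_nodes() < 2:
            return pd.Series(0.0, index=list(h.nodes))
        full = _MEASURE_FUNCS[measure](g)
        return full.loc[list(h.nodes)]
    raise ValueError(f"unknown representation {representation!r}")


def classify_strength(v: float) -> str | None:
    """Band a centrality value: weak <= 0.3 < moderate < 0.7 <= strong.

    Undefined values (NaN) return None.
    """
    if v is None or (isinstance(v, float) and v != v):
        return None
    if not -1e-9 <= v <= 1 + 1e-9:
        raise ValueError(f"centrality value outside [0, 1]: {v}")
    if v <= 0.3:
        return "weak"
    if v >= 0.7:
        return "strong"
    return "moderate"


def centrality_report(
    source: nx.Graph | Hypergraph, representation: str = "two_section"
) -> pd.DataFrame:
    """All four measures plus strength labels, one row per node.

    Mirrors the published centrality tables: four value columns followed by
    four strength-label columns.
    """
    if isinstance(source, Hypergraph):
        series = {m: hypergraph_centrality(source, m, representation) for m in MEASURES}
    else:
        series = {m: _MEASURE_FUNCS[m](source) for m in MEASURES}
    report = pd.DataFrame(series)
    for m in MEASURES:
        report[f"{m}_strength"] = report[m].map(classify_strength)
    return report
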