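"""Thresholded graph and hypergraph construction from association matrices.

An edge joins two variables when the absolute association meets the domain
threshold (0.2 for the sociodemographic and nutritional-status domains, 0.3
for the metabolic domain; 0.5 for visualization exports).  Hyperedges —
node subsets of arbitrary size representing polyadic interactions — are
derived from the thresholded graph either as its maximal cliques (default)
or as ego sets (each non-isolated node together with its neighbourhood).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .association import AssociationMatrix

__all__ = [
    "Hypergraph",
    "build_graph",
    "build_hypergraph",
    "DOMAIN_THRESHOLDS",
    "VISUALIZATION_THRESHOLD",
    "write_edgelist",
    "write_graphml",
    "write_incidence",
]

#: per-domain analysis thresholds
DOMAIN_THRESHOLDS = {"sociodemographic": 0.2, "nutritional": 0.2, "metabolic": 0.3}
#: threshold used for network visualization exports
VISUALIZATION_THRESHOLD = 0.5


@dataclass(frozen=True)
class Hypergraph:
    """Node set plus identified hyperedges (frozensets of size >= 2)."""

    nodes: tuple[str, ...]
    hyperedges: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        seen = set()
        for eid, members in self.hyperedges:
            if len(members) < 2:
                raise ValueError(f"hyperedge {eid} has fewer than 2 members")
            if not members <= node_set:
                raise ValueError(f"hyperedge {eid} contains undeclared nodes")
            if members in seen:
                raise ValueError(f"duplicate hyperedge {sorted(members)}")
            seen.add(members)

    @property
    def m(self) -> int:
        return len(self.hyperedges)

    def two_section(self) -> nx.Graph:
        """Plain graph joining every pair of nodes sharing >= 1 hyperedge."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, members in self.hyperedges:
            ordered = sorted(members)
            for i, a in enumerate(ordered):
                for b in ordered[i + 1 :]:
                    g.add_edge(a, b)
        return g

    def incidence_bipartite(self) -> nx.Graph:
        """Bipartite node-hyperedge incidence graph.

        Hyperedge vertices carry their identifier prefixed with ``he:`` to
        avoid clashing with variable names.
        """
        g = nx.Graph()
        g.add_nodes_from(self.nodes, bipartite=0)
        for eid, members in self.hyperedges:
            he = f"he:{eid}"
            g.add_node(he, bipartite=1)
            for v in members:
                g.add_edge(v, he)
        return g


def build_graph(matrix: AssociationMatrix, threshold: float) -> nx.Graph:
    """Graph with an edge wherever \\|association\\| >= threshold.

    All variables appear as nodes (isolates retained); edges carry the
    absolute association as ``weight`` and the signed value as ``signed``.
    Undefined (NaN) entries never produce edges.
    """
    if not 0 <= threshold:
        raise ValueError("threshold must be nonnegative")
    g = nx.Graph()
    g.add_nodes_from(matrix.variables)
    vals = matrix.values
    for i, a in enumerate(matrix.variables):
        for b in matrix.variables[i + 1 :]:
            v = vals.loc[a, b]
            if v == v and abs(v) >= threshold:  # NaN-safe
                g.add_edge(a, b, weight=abs(float(v)), signed=float(v))
    return g


def build_hypergraph(
    matrix: AssociationMatrix, threshold: float, mode: str = "maximal_clique"
) -> Hypergraph:
    """Hyperedges from the thresholded graph.

    ``maximal_clique`` (default): the maximal cliques of size >= 2 — every
    group of mutually associated variables becomes one polyadic interaction.
    ``ego``: one hyperedge per non-isolated node, the node plus its
    neighbourhood (duplicates collapsed).
    """
    g = build_graph(matrix, threshold)
    if mode == "maximal_clique":
        raw = [frozenset(c) for c in nx.find_cliques(g) if len(c) >= 2]
    elif mode == "ego":
        raw = []
        for v in g.nodes:
            nbrs = set(g.neighbors(v))
            if nbrs:
                raw.append(frozenset({v} | nbrs))
    else:
        raise ValueError(f"unknown hyperedge mode {mode!r}")
    uniq = sorted(set(raw), key=lambda s: (sorted(s), len(s)))
    edges = tuple((f"e{i + 1}", members) for i, members in enumerate(uniq))
    return Hypergraph(tuple(matrix.variables), edges)


def write_edgelist(g: nx.Graph, path: str | Path) -> None:
    """Tab-separated edge list: node, node, weight."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for a, b, d in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d.get('weight', 1.0):.6g}\n")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def write_incidence(h: Hypergraph, path: str | Path) -> None:
    """Hyperedge incidence list as JSON: id -> sorted member names."""
    payload = {
        "nodes": list(h.nodes),
        "hyperedges": {eid: sorted(members) for eid, members in h.hyperedges},
    }
    Path(path).write_text(json.dumps(payload, indent=1))
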