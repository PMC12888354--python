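"""Model/Results interface over the association-network pipeline.

:class:`AssociationNetworkModel` is constructed from a cohort (a
:class:`~fanet.synthetic.CohortTable` or a plain DataFrame with a kind
declaration per variable) together with the network-construction settings
— threshold, hyperedge rule, missing-data policy.  ``fit()`` runs the
pipeline (association matrix, collinearity pruning, graph, hypergraph,
centralities) and returns a :class:`NetworkResults` carrying the estimates;
bootstrap stability and a formatted summary hang off the results object.

>>> from fanet import AssociationNetworkModel, synthetic
>>> cohort = synthetic.generate_cohort(synthetic.default_study_specs(), seed=1)
>>> res = AssociationNetworkModel.from_cohort(
...     cohort, ["food_addiction", "age", "race", "socioeconomic_class"],
...     threshold=0.2).fit()
>>> res.centrality  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .association import AssociationMatrix, MissingPolicy, build_matrix, prune_collinear
from .centrality import MEASURES, centrality_report
from .netbuild import Hypergraph, build_graph, build_hypergraph
from .stability import stability_analysis
from .synthetic import CohortTable

__all__ = ["AssociationNetworkModel", "NetworkResults"]


class AssociationNetworkModel:
    """Mixed-type association network of a cohort at a fixed threshold.

    Parameters
    ----------
    cohort
        CohortTable (carries variable kinds) or plain DataFrame plus a
        ``kinds`` mapping.
    threshold
        Absolute-association edge threshold (0.2 for sociodemographic and
        nutritional domains, 0.3 metabolic in the reference analysis).
    hyperedge_mode
        ``maximal_clique`` (default) or ``ego``.
    policy
        Missing-data policy for matrix construction.
    prune_cutoff
        Collinearity cutoff; variables are greedily removed until no
        absolute association reaches it.
    """

    def __init__(
        self,
        cohort: CohortTable | pd.DataFrame,
        kinds: Mapping[str, str] | None = None,
        threshold: float = 0.2,
        hyperedge_mode: str = "maximal_clique",
        policy: MissingPolicy | None = None,
        prune_cutoff: float = 0.90,
        name: str = "",
    ) -> None:
        self.cohort = cohort
        self.kinds = kinds
        self.threshold = threshold
        self.hyperedge_mode = hyperedge_mode
        self.policy = policy or MissingPolicy()
        self.prune_cutoff = prune_cutoff
        self.name = name

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, kinds: Mapping[str, str], **kwargs
    ) -> "AssociationNetworkModel":
        return cls(data, kinds=kinds, **kwargs)

    @classmethod
    def from_cohort(
        cls, cohort: CohortTable, variables: Sequence[str] | None = None, **kwargs
    ) -> "AssociationNetworkModel":
        if variables is not None:
            cohort = cohort.subset(variables)
        return cls(cohort, **kwargs)

    def fit(self) -> "NetworkResults":
        matrix = build_matrix(self.cohort, kinds=self.kinds, policy=self.policy)
        pruned, removed = prune_collinear(matrix, self.prune_cutoff)
        graph = build_graph(pruned, self.threshold)
        hypergraph = build_hypergraph(pruned, self.threshold, self.hyperedge_mode)
        return NetworkResults(
            model=self,
            association=pruned,
            association_full=matrix,
            removed=removed,
            graph=graph,
            hypergraph=hypergraph,
        )


@dataclass
class NetworkResults:
    """Fitted association network: matrices, networks, centralities."""

    model: AssociationNetworkModel
    association: AssociationMatrix
    association_full: AssociationMatrix
    removed: list[tuple[str, str]]
    graph: nx.Graph
    hypergraph: Hypergraph
    _centrality: pd.DataFrame | None = field(default=None, repr=False)
    _hg_centrality: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def centrality(self) -> pd.DataFrame:
        """Graph centrality report (four measures + strength labels)."""
        if self._centrality is None:
            self._centrality = centrality_report(self.graph)
        return self._centrality

    @property
    def hypergraph_centrality(self) -> pd.DataFrame:
        """Hypergraph (two-section) centrality report."""
        if self._hg_centrality is None:
            self._hg_centrality = centrality_report(self.hypergraph)
        return self._hg_centrality

    def bootstrap_stability(
        self, B: int = 500, scheme: str = "matrix_nodes", seed: int | None = None
    ) -> pd.DataFrame:
        """Bootstrap stability summary (per-measure Spearman r_s table)."""
        source = self.association if scheme == "matrix_nodes" else self.model.cohort
        summary, _, _ = stability_analysis(
            source,
            B=B,
            scheme=scheme,
            threshold=self.model.threshold,
            seed=seed,
            mode=self.model.hyperedge_mode,
        )
        return summary

    def summary(self) -> str:
        """Human-readable fit summary in the style of a results table."""
        m = self.model
        lines = [
            f"Association network{': ' + m.name if m.name else ''}",
            "=" * 64,
            f"Variables: {self.association.p} (removed for collinearity: "
            f"{', '.join(v for v, _ in self.removed) or 'none'})",
            f"Threshold: {m.threshold}   Hyperedge rule: {m.hyperedge_mode}",
            f"Edges: {self.graph.number_of_edges()}   "
            f"Hyperedges: {self.hypergraph.m}",
            "",
            "Graph centrality",
            "-" * 64,
            self.centrality[list(MEASURES)].round(3).to_string(),
            "",
            "Hypergraph (two-section) centrality",
            "-" * 64,
            self.hypergraph_centrality[list(MEASURES)].round(3).to_string(),
        ]
        return "\n".join(lines)
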