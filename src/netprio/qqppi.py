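"""Query-query PPI (QQPPI) network extraction.

The QQPPI network is the induced subgraph of the reference interactome
on the query genes (here, differentially expressed genes): only direct
interactions among queries survive. Distance-based centralities need a
connected graph, so analysis is restricted to the largest connected
component; up/down annotations are carried for reporting only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class QQPPINetwork:
    graph: nx.Graph
    direction: dict = field(default_factory=dict)
    n_queries_missing: int = 0

    @property
    def analysis_component(self) -> frozenset:
        """Node set of the largest connected component (the centrality domain)."""
        if self.graph.number_of_nodes() == 0:
            return frozenset()
        return frozenset(_best_component(self.graph))

    def node_table(self) -> pd.DataFrame:
        component = self.analysis_component
        nodes = sorted(self.graph)
        return pd.DataFrame(
            {
                "symbol": nodes,
                "direction": [self.direction.get(v, "") for v in nodes],
                "in_analysis_component": [v in component for v in nodes],
            }
        )


def _best_component(graph: nx.Graph) -> set:
    """Largest component; ties broken by lexicographically smallest member."""
    components = [set(c) for c in nx.connected_components(graph)]
    return min(components, key=lambda c: (-len(c), min(c)))


def extract_qqppi(interactome: nx.Graph, degs: pd.DataFrame) -> QQPPINetwork:
    """Induce the interactome subgraph on DEG-mapped query genes.

    ``degs`` is a DEG table with ``gene`` and ``direction`` columns.
    Queries absent from the interactome are counted and logged; zero
    mapped queries is an error.
    """
    if interactome.number_of_nodes() == 0:
        raise ValueError("empty interactome")
    if len(degs) == 0:
        raise ValueError("zero queries: empty DEG table")
    queries = set(degs["gene"])
    present = queries & set(interactome.nodes)
    if not present:
        raise ValueError("zero queries found in the interactome")
    missing = len(queries) - len(present)
    if missing:
        logger.info("%d quer%s not present in the interactome", missing,
                    "y" if missing == 1 else "ies")
    graph = interactome.subgraph(present).copy()
    direction = {
        gene: direction
        for gene, direction in zip(degs["gene"], degs["direction"])
        if gene in present
    }
    return QQPPINetwork(graph=graph, direction=direction, n_queries_missing=missing)


def largest_component(network: QQPPINetwork) -> QQPPINetwork:
    """Restrict to the largest connected component (lexicographic tie-break)."""
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty QQPPI network")
    keep = _best_component(network.graph)
    excluded = network.graph.number_of_nodes() - len(keep)
    if excluded:
        logger.info("excluding %d node(s) outside the largest component", excluded)
    graph = network.graph.subgraph(keep).copy()
    direction = {v: d for v, d in network.direction.items() if v in keep}
    return QQPPINetwork(graph=graph, direction=direction,
                        n_queries_missing=network.n_queries_missing)
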