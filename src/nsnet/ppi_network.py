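"""Weighted undirected gene interaction network built from a confidence-scored edge table.

The network nodes are gene symbols (typically the genes carrying qualifying
ultra-rare LoF variants) and the edges carry an interaction confidence in
[0, 1], in the style of a STRING combined-score edge list rescaled to [0, 1].
Genes from the input gene set with no surviving edge are kept as degree-0
nodes so that downstream per-community case counts span every qualifying gene.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: conventional STRING "medium confidence" cutoff; the threshold is
#: configurable everywhere it is consumed.
DEFAULT_CONFIDENCE_MIN = 0.4


class Network:
    """Undirected weighted gene graph.

    Invariants: no self-loops, no duplicate edges, weights in [0, 1],
    undirected symmetry. Backed by a :class:`networkx.Graph`.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -------------------------------------------------

    def add_node(self, gene: str) -> None:
        self.graph.add_node(gene)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ValueError(f"self-loop rejected: {a}")
        if not 0.0 <= weight <= 1.0:
            raise ValueError(f"confidence out of [0,1]: {weight!r} for {a}-{b}")
        self.graph.add_edge(a, b, weight=float(weight))

    # -- queries -------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for a, b, d in self.graph.edges(data=True):
            yield a, b, d["weight"]

    def neighbors(self, gene: str) -> list[str]:
        return list(self.graph.neighbors(gene))

    def weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


def build_network(
    edge_table: pd.DataFrame,
    gene_set: Iterable[str],
    confidence_min: float = DEFAULT_CONFIDENCE_MIN,
) -> Network:
    """Restrict a confidence-scored edge table to a gene set.

    Parameters
    ----------
    edge_table
        Columns ``gene_a``, ``gene_b``, ``confidence``. Rows with an
        unparseable confidence are rejected and logged, not fatal.
    gene_set
        Genes to retain; isolated members become degree-0 nodes.
    confidence_min
        Keep edges with ``confidence >= confidence_min``; must lie in [0, 1].
    """
    if not 0.0 <= confidence_min <= 1.0:
        raise ValueError(f"confidence_min must be in [0,1], got {confidence_min}")
    genes = {str(g) for g in gene_set}
    net = Network()
    for g in sorted(genes):
        net.add_node(g)
    n_rejected = 0
    for row in edge_table.itertuples(index=False):
        a, b = str(row.gene_a), str(row.gene_b)
        try:
            w = float(row.confidence)
            if not 0.0 <= w <= 1.0:
                raise ValueError
        except (TypeError, ValueError):
            n_rejected += 1
            logger.warning("edge %s-%s rejected: bad confidence %r", a, b, row.confidence)
            continue
        if a == b or a not in genes or b not in genes or w < confidence_min:
            continue
        net.add_edge(a, b, w)
    logger.info(
        "build_network: %d nodes, %d edges kept at confidence >= %.3g (%d rows rejected)",
        net.n_nodes, net.n_edges, confidence_min, n_rejected,
    )
    return net


def network_summary(net: Network) -> dict:
    """Node/edge counts, per-node degree table and average local clustering.

    The local clustering coefficient of a node with degree < 2 is 0, and the
    average is taken over all nodes (including isolated ones).
    """
    clustering = nx.clustering(net.graph)  # networkx returns 0.0 for deg<2
    degree_table = pd.DataFrame(
        {
            "gene": list(net.graph.nodes),
            "degree": [net.graph.degree[n] for n in net.graph.nodes],
            "weighted_degree": [net.graph.degree(weight="weight")[n] for n in net.graph.nodes],
            "clustering": [clustering[n] for n in net.graph.nodes],
        }
    ).sort_values(["degree", "gene"], ascending=[False, True], ignore_index=True)
    avg_clust = float(sum(clustering.values()) / net.n_nodes) if net.n_nodes else 0.0
    return {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "degree_table": degree_table,
        "avg_clustering": avg_clust,
    }


def connected_components(net: Network) -> dict[str, int]:
    """Map gene -> component label, components labelled 0,1,... by their
    lexicographically smallest member."""
    comps = [sorted(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: c[0])
    return {g: i for i, comp in enumerate(comps) for g in comp}


# -- I/O ---------------------------------------------------------------


def read_edge_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    expected = {"gene_a", "gene_b", "confidence"}
    if not expected.issubset(df.columns):
        raise ValueError(f"edge table {path} must have columns {sorted(expected)}")
    return df


def write_edge_list(net: Network, path: str | Path) -> None:
    rows = sorted((min(a, b), max(a, b), w) for a, b, w in net.edges())
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(net: Network, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))
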