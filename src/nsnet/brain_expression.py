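"""Brain-region expression enrichment of communities over a part_of anatomy DAG.

The anatomy is a rooted DAG ("brain" at the root) whose edges are exclusively
part_of relations, in the style of the brain sub-graph of a vertebrate
anatomy ontology. Expression calls (gene, term) are propagated up the DAG
(true-path rule), each non-root term is tested for overrepresentation of a
community's genes with a parent-child decorrelated hypergeometric test, and
per-community p-values are BH-converted to Q-values. Rows (regions) with at
least one Q below the display threshold make up the heatmap matrix, whose
columns (communities) are ordered by average-linkage hierarchical clustering
of their -log10(Q) profiles.

The parent-child test conditions each term on its parents: the sampling
universe is the set of genes annotated (after propagation) to the union of
the term's parents, which removes the trivial significance a term inherits
from an already-enriched parent. An intersection variant (universe = genes
annotated to every parent) is available by flag.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage

from .enrichment import bh_adjust, hypergeom_upper

logger = logging.getLogger(__name__)


class AnatomyDAG:
    """Rooted part_of DAG; edges run child -> parent."""

    def __init__(self, edges: Iterable[tuple[str, str]], names: Mapping[str, str] | None = None):
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("anatomy relations contain a cycle")
        roots = [t for t in g.nodes if g.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"anatomy DAG must have exactly one root, found {sorted(roots)}")
        self.graph = g
        self.root = roots[0]
        self.names = dict(names or {})

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def parents(self, term: str) -> list[str]:
        return sorted(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        return nx.descendants(self.graph, term)  # edges point child->parent

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnatomyDAG":
        df = pd.read_csv(path, sep="\t", comment="#")
        df.columns = [c.lower() for c in df.columns]
        return cls(list(zip(df["child"], df["parent"])))

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted(self.graph.edges)
        pd.DataFrame(rows, columns=["child", "parent"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression calls
# ---------------------------------------------------------------------------


def read_calls(path: str | Path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    return {(str(r.gene), str(r.term)) for r in df.itertuples(index=False)}


def write_calls(calls: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(sorted(calls), columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


def propagate_calls(dag: AnatomyDAG, calls: set[tuple[str, str]]) -> set[tuple[str, str]]:
    """Close calls upward: a gene present at a term is present at all its
    ancestors (true-path rule). Idempotent."""
    unknown = {t for _, t in calls if t not in dag.graph}
    if unknown:
        raise ValueError(f"expression call on unknown term(s): {sorted(unknown)[:5]}")
    closed = set(calls)
    for gene, term in calls:
        for anc in dag.ancestors(term):
            closed.add((gene, anc))
    return closed


def _genes_by_term(closed: set[tuple[str, str]]) -> dict[str, set[str]]:
    by_term: dict[str, set[str]] = {}
    for gene, term in closed:
        by_term.setdefault(term, set()).add(gene)
    return by_term


# ---------------------------------------------------------------------------
# parent-child decorrelated test
# ---------------------------------------------------------------------------


def parent_child_test(
    term: str,
    query_genes: set[str],
    dag: AnatomyDAG,
    closed_calls: set[tuple[str, str]],
    variant: str = "union",
) -> float:
    """Hypergeometric upper-tail p of the query in the parent-conditioned universe.

    The universe is the union (default) or intersection of the gene sets
    annotated to the term's parents after propagation; draws are the query
    genes inside that universe and successes the genes annotated to the term.
    On a flat DAG (all terms children of the root) this reduces to the plain
    hypergeometric test against the root universe. A term with no
    parent-annotated genes yields p = 1 (flagged in the log).
    """
    if term == dag.root:
        raise ValueError("parent-child test is undefined for the root term")
    if variant not in ("union", "intersection"):
        raise ValueError(f"unknown parent-child variant {variant!r}")
    by_term = _genes_by_term(closed_calls)
    parents = dag.parents(term)
    parent_sets = [by_term.get(p, set()) for p in parents]
    if variant == "union":
        universe = set().union(*parent_sets) if parent_sets else set()
    else:
        universe = set.intersection(*parent_sets) if parent_sets else set()
    if not universe:
        logger.warning("term %s: no parent-annotated genes; p = 1", term)
        return 1.0
    term_genes = by_term.get(term, set()) & universe
    query_u = query_genes & universe
    k = len(query_u & term_genes)
    return hypergeom_upper(k, len(term_genes), len(query_u), len(universe))


# ---------------------------------------------------------------------------
# community x region matrix
# ---------------------------------------------------------------------------


def region_enrichment(
    communities: Mapping[int, set[str]],
    dag: AnatomyDAG,
    calls: set[tuple[str, str]],
    variant: str = "union",
    display_q: float = 0.05,
) -> pd.DataFrame:
    """Q-value matrix, rows = non-root regions, columns = communities.

    Per community every non-root term is tested with the parent-child test
    and the p-values are BH-adjusted to Q across terms within that community.
    Only rows with at least one Q < ``display_q`` are retained (the full
    matrix is available via ``display_q=None``).
    """
    closed = propagate_calls(dag, calls)
    terms = [t for t in dag.terms if t != dag.root]
    data = {}
    for c in sorted(communities):
        genes = communities[c]
        if not genes or not any((g, dag.root) in closed for g in genes):
            logger.warning("community %s has no expressed genes; column of 1s", c)
            data[c] = pd.Series(1.0, index=terms)
            continue
        p = [parent_child_test(t, genes, dag, closed, variant=variant) for t in terms]
        data[c] = pd.Series(bh_adjust(p), index=terms)
    matrix = pd.DataFrame(data)
    matrix.index.name = "region"
    if display_q is not None:
        keep = (matrix < display_q).any(axis=1)
        matrix = matrix[keep]
    return matrix


def cluster_communities(matrix: pd.DataFrame) -> tuple[list, np.ndarray]:
    """Column order and linkage from average-linkage clustering.

    Distances are Euclidean between -log10(Q) column profiles; with a single
    column the order is trivial. Leaf order is scipy's deterministic
    dendrogram order (ties resolved by the smallest column index, i.e.
    smallest community label first).
    """
    cols = list(matrix.columns)
    if len(cols) < 2:
        return cols, np.empty((0, 4))
    profiles = -np.log10(matrix.to_numpy(dtype=float)).T  # rows = communities
    link = linkage(profiles, method="average", metric="euclidean")
    order = dendrogram(link, no_plot=True)["leaves"]
    return [cols[i] for i in order], link


def plot_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    """Render the region x community heatmap (columns in clustered order)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    order, _ = cluster_communities(matrix)
    scores = -np.log10(matrix[order].astype(float))
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(order), 1.0 + 0.3 * len(matrix)))
    sns.heatmap(scores, cmap="Blues", ax=ax, cbar_kws={"label": "-log10(Q)"})
    ax.set_xlabel("community")
    ax.set_ylabel("brain region")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
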