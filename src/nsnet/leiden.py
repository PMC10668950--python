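"""Leiden community detection on a weighted undirected network.

The algorithm iterates three phases until a fixed point: queue-based local
moving of nodes between communities, a stochastic refinement step inside each
community, and aggregation of the refined partition into a smaller graph.
Refinement is what distinguishes Leiden from Louvain: aggregation acts on the
refined sub-communities, which guarantees that every returned community
induces a connected subgraph (degree-0 nodes remain singletons).

Two quality functions are supported:

* ``modularity`` (default): the weighted Newman-Girvan form

      Q = sum_c [ w_c / m  -  gamma * (s_c / 2m)^2 ]

  with ``m`` the total edge weight, ``w_c`` the intra-community weight and
  ``s_c`` the summed weighted degree of community ``c``.
* ``cpm``: the constant Potts model,
  ``Q = sum_c [ w_c - gamma * n_c (n_c - 1) / 2 ]`` with ``n_c`` the number
  of original nodes in ``c`` — resolution-limit-free, useful for
  sensitivity runs.

All randomness (node visit order, stochastic refinement) flows from a single
seeded generator, so results are deterministic given the seed. Ties in
move gain are broken toward the smallest community label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ppi_network import Network

_EPS = 1e-12


@dataclass
class QualityConfig:
    """Parameters of the optimisation.

    resolution > 0 scales the null-model penalty (gamma); theta > 0 is the
    refinement temperature — small theta makes refinement near-greedy.
    """

    quality: str = "modularity"
    resolution: float = 1.0
    theta: float = 0.01
    max_passes: int = 50
    seed: int = 0
    n_restarts: int = 5

    def __post_init__(self):
        if self.quality not in ("modularity", "cpm"):
            raise ValueError(f"unknown quality function: {self.quality!r}")
        if self.resolution <= 0 or self.theta <= 0 or self.max_passes < 1:
            raise ValueError("resolution, theta must be > 0 and max_passes >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class Partition:
    """Node -> community assignment with the quality at convergence."""

    membership: dict[str, int]
    quality: float
    n_passes: int
    quality_history: list[float] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.membership.items():
            out.setdefault(c, []).append(node)
        return {c: sorted(members) for c, members in out.items()}


# ---------------------------------------------------------------------------
# internal multigraph representation (supports self-loops and node sizes,
# both needed for aggregated graphs)
# ---------------------------------------------------------------------------


class _Graph:
    def __init__(self, n: int):
        self.n = n
        self.nbrs: list[dict[int, float]] = [dict() for _ in range(n)]
        self.loops = np.zeros(n)          # self-loop weight (counted once)
        self.sizes = np.ones(n, dtype=np.int64)   # original-node counts

    @classmethod
    def from_network(cls, net: Network, node_order: Sequence[str]) -> "_Graph":
        index = {g: i for i, g in enumerate(node_order)}
        g = cls(len(node_order))
        for a, b, w in net.edges():
            i, j = index[a], index[b]
            g.nbrs[i][j] = g.nbrs[i].get(j, 0.0) + w
            g.nbrs[j][i] = g.nbrs[j].get(i, 0.0) + w
        return g

    @property
    def strengths(self) -> np.ndarray:
        return np.array([sum(nb.values()) for nb in self.nbrs]) + 2.0 * self.loops

    @property
    def total_weight(self) -> float:
        """Total edge weight m (each edge and loop counted once)."""
        return float(sum(sum(nb.values()) for nb in self.nbrs)) / 2.0 + float(self.loops.sum())


def _quality_value(g: _Graph, memb: np.ndarray, cfg: QualityConfig) -> float:
    gamma = cfg.resolution
    labels = np.unique(memb)
    w_in = {c: 0.0 for c in labels}
    for i in range(g.n):
        w_in[memb[i]] += g.loops[i]
        for j, w in g.nbrs[i].items():
            if j > i and memb[j] == memb[i]:
                w_in[memb[i]] += w
    if cfg.quality == "modularity":
        m = g.total_weight
        if m <= 0:
            return 0.0
        strengths = g.strengths
        s_c = {c: 0.0 for c in labels}
        for i in range(g.n):
            s_c[memb[i]] += strengths[i]
        return float(sum(w_in[c] / m - gamma * (s_c[c] / (2.0 * m)) ** 2 for c in labels))
    # CPM
    n_c = {c: 0 for c in labels}
    for i in range(g.n):
        n_c[memb[i]] += int(g.sizes[i])
    return float(sum(w_in[c] - gamma * n_c[c] * (n_c[c] - 1) / 2.0 for c in labels))


# ---------------------------------------------------------------------------
# public quality functions on gene-labelled partitions
# ---------------------------------------------------------------------------


def _as_graph(net: Network) -> tuple[_Graph, list[str]]:
    order = list(net.nodes)
    return _Graph.from_network(net, order), order


def _check_cover(net: Network, partition: Mapping[str, int]) -> None:
    missing = [n for n in net.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")


def modularity(net: Network, partition: Mapping[str, int], resolution: float = 1.0) -> float:
    """Weighted modularity of a partition; 0 for an edgeless network."""
    _check_cover(net, partition)
    g, order = _as_graph(net)
    memb = np.array([partition[n] for n in order])
    return _quality_value(g, memb, QualityConfig(quality="modularity", resolution=resolution))


def cpm_quality(net: Network, partition: Mapping[str, int], resolution: float = 1.0) -> float:
    """Constant Potts model quality of a partition."""
    _check_cover(net, partition)
    g, order = _as_graph(net)
    memb = np.array([partition[n] for n in order])
    return _quality_value(g, memb, QualityConfig(quality="cpm", resolution=resolution))


# ---------------------------------------------------------------------------
# phase 1: queue-based local moving
# ---------------------------------------------------------------------------


def _local_move(g: _Graph, memb: np.ndarray, cfg: QualityConfig, rng: np.random.Generator) -> int:
    gamma = cfg.resolution
    m = g.total_weight
    if m <= 0:
        return 0
    strengths = g.strengths
    comm_strength: dict[int, float] = {}
    comm_sizes: dict[int, int] = {}
    for i in range(g.n):
        comm_strength[memb[i]] = comm_strength.get(memb[i], 0.0) + strengths[i]
        comm_sizes[memb[i]] = comm_sizes.get(memb[i], 0) + int(g.sizes[i])

    order = rng.permutation(g.n)
    queue = list(order)
    in_queue = np.ones(g.n, dtype=bool)
    head = 0
    n_moves = 0
    free_labels: list[int] = []
    next_label = int(memb.max()) + 1 if g.n else 0

    while head < len(queue):
        v = queue[head]
        head += 1
        in_queue[v] = False
        old = int(memb[v])
        # weight from v to each neighbouring community
        w_to: dict[int, float] = {old: 0.0}
        for j, w in g.nbrs[v].items():
            c = int(memb[j])
            w_to[c] = w_to.get(c, 0.0) + w
        # remove v from its community
        comm_strength[old] -= strengths[v]
        comm_sizes[old] -= int(g.sizes[v])

        def gain(c: int, w_vc: float) -> float:
            if cfg.quality == "modularity":
                return w_vc / m - gamma * strengths[v] * comm_strength.get(c, 0.0) / (2.0 * m * m)
            return w_vc - gamma * g.sizes[v] * comm_sizes.get(c, 0)

        stay_gain = gain(old, w_to[old])
        best_c, best_gain = old, stay_gain
        empty = free_labels[-1] if free_labels else next_label
        candidates = sorted(w_to) + ([empty] if comm_sizes[old] > 0 else [])
        for c in candidates:
            if c == old:
                continue
            gn = gain(c, w_to.get(c, 0.0))
            if gn > best_gain + _EPS or (abs(gn - best_gain) <= _EPS and best_c != old and c < best_c):
                best_c, best_gain = c, gn
        memb[v] = best_c
        comm_strength[best_c] = comm_strength.get(best_c, 0.0) + strengths[v]
        comm_sizes[best_c] = comm_sizes.get(best_c, 0) + int(g.sizes[v])
        if best_c != old:
            n_moves += 1
            if best_c == empty:
                if free_labels:
                    free_labels.pop()
                else:
                    next_label += 1
            if comm_sizes[old] == 0:
                free_labels.append(old)
            for j in g.nbrs[v]:
                if not in_queue[j] and memb[j] != best_c:
                    queue.append(j)
                    in_queue[j] = True
    return n_moves


# ---------------------------------------------------------------------------
# phase 2: refinement inside each community
# ---------------------------------------------------------------------------


def _refine(g: _Graph, memb: np.ndarray, cfg: QualityConfig, rng: np.random.Generator) -> np.ndarray:
    gamma = cfg.resolution
    m = g.total_weight
    strengths = g.strengths
    refined = np.arange(g.n)

    comms: dict[int, list[int]] = {}
    for i in range(g.n):
        comms.setdefault(int(memb[i]), []).append(i)

    for c, members in sorted(comms.items()):
        if len(members) < 2:
            continue
        member_set = set(members)
        k_C = float(strengths[list(member_set)].sum())
        sz_C = int(g.sizes[list(member_set)].sum())
        # per-node weight to the rest of C
        w_rest = {}
        for v in members:
            w_rest[v] = sum(w for j, w in g.nbrs[v].items() if j in member_set)

        def well_connected_node(v: int) -> bool:
            if cfg.quality == "modularity":
                thr = gamma * strengths[v] * (k_C - strengths[v]) / (2.0 * m) if m > 0 else 0.0
            else:
                thr = gamma * g.sizes[v] * (sz_C - g.sizes[v])
            return w_rest[v] >= thr - _EPS

        # refined sub-communities, initially singletons
        sub: dict[int, dict] = {
            v: {"members": {v}, "k": float(strengths[v]), "sz": int(g.sizes[v]), "w_out": w_rest[v]}
            for v in members
        }
        for v in rng.permutation(members):
            v = int(v)
            if len(sub[refined[v]]["members"]) > 1 or not well_connected_node(v):
                continue
            w_to: dict[int, float] = {}
            for j, w in g.nbrs[v].items():
                if j in member_set:
                    r = int(refined[j])
                    w_to[r] = w_to.get(r, 0.0) + w
            cand_labels, gains = [], []
            for r, w_vr in sorted(w_to.items()):
                if r == refined[v]:
                    continue
                d = sub[r]
                if cfg.quality == "modularity":
                    thr = gamma * d["k"] * (k_C - d["k"]) / (2.0 * m) if m > 0 else 0.0
                    gn = w_vr / m - gamma * strengths[v] * d["k"] / (2.0 * m * m)
                else:
                    thr = gamma * d["sz"] * (sz_C - d["sz"])
                    gn = w_vr - gamma * g.sizes[v] * d["sz"]
                if d["w_out"] >= thr - _EPS and gn > -_EPS:
                    cand_labels.append(r)
                    gains.append(max(gn, 0.0))
            if not cand_labels:
                continue
            # stay-singleton option, gain 0
            cand_labels.append(int(refined[v]))
            gains.append(0.0)
            logits = np.array(gains) / cfg.theta
            probs = np.exp(logits - logits.max())
            probs /= probs.sum()
            target = int(cand_labels[rng.choice(len(cand_labels), p=probs)])
            if target == refined[v]:
                continue
            src = int(refined[v])
            d = sub[target]
            w_vd = w_to.get(target, 0.0)
            d["members"].add(v)
            d["k"] += float(strengths[v])
            d["sz"] += int(g.sizes[v])
            d["w_out"] = d["w_out"] + w_rest[v] - 2.0 * w_vd
            del sub[src]
            refined[v] = target
    return refined


# ---------------------------------------------------------------------------
# phase 3: aggregation
# ---------------------------------------------------------------------------


def _aggregate(
    g: _Graph, refined: np.ndarray, memb: np.ndarray
) -> tuple[_Graph, np.ndarray, np.ndarray]:
    """Collapse refined communities into nodes.

    Returns (aggregated graph, membership of aggregated nodes in the
    unrefined partition, mapping node -> aggregated node). Total edge weight
    is conserved: intra-refined weight becomes self-loop weight.
    """
    labels: list[int] = []
    compact: dict[int, int] = {}
    for i in range(g.n):
        r = int(refined[i])
        if r not in compact:
            compact[r] = len(labels)
            labels.append(r)
    node_map = np.array([compact[int(refined[i])] for i in range(g.n)])

    agg = _Graph(len(labels))
    agg.sizes = np.zeros(len(labels), dtype=np.int64)
    agg_memb = np.zeros(len(labels), dtype=np.int64)
    for i in range(g.n):
        a = node_map[i]
        agg.sizes[a] += g.sizes[i]
        agg.loops[a] += g.loops[i]
        agg_memb[a] = memb[i]
        for j, w in g.nbrs[i].items():
            b = node_map[j]
            if a == b:
                # each intra edge is visited from both endpoints; count once
                if j > i:
                    agg.loops[a] += w
            else:
                agg.nbrs[a][b] = agg.nbrs[a].get(b, 0.0) + w
    return agg, agg_memb, node_map


def refine_and_aggregate(
    net: Network, partition: Mapping[str, int], cfg: QualityConfig | None = None
) -> tuple[_Graph, np.ndarray, dict[str, int]]:
    """One refinement + aggregation step on a gene-labelled partition.

    Returns the aggregated internal graph, the membership of each aggregated
    node in the input partition, and the gene -> aggregated-node mapping.
    Exposed mainly for inspection and testing; :func:`leiden` drives the full
    loop.
    """
    cfg = cfg or QualityConfig()
    _check_cover(net, partition)
    g, order = _as_graph(net)
    memb = np.array([partition[n] for n in order])
    rng = np.random.default_rng(cfg.seed)
    refined = _refine(g, memb, cfg, rng)
    agg, agg_memb, node_map = _aggregate(g, refined, memb)
    gene_map = {gene: int(node_map[i]) for i, gene in enumerate(order)}
    return agg, agg_memb, gene_map


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def leiden(net: Network, cfg: QualityConfig | None = None) -> Partition:
    """Run the full Leiden loop and return the flat partition.

    Quality is non-decreasing across passes and each run terminates at a
    fixed point (every community is a single aggregated node) or after
    ``max_passes``. Single-node moving only guarantees a local optimum, so
    ``n_restarts`` independent runs are made with visit orders derived from
    the seed and the best-quality partition is returned (first run wins
    ties) — still fully deterministic given the seed.
    """
    cfg = cfg or QualityConfig()
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    best: Partition | None = None
    for restart in range(cfg.n_restarts):
        cand = _leiden_once(net, cfg, np.random.default_rng([cfg.seed, restart]))
        if best is None or cand.quality > best.quality + _EPS:
            best = cand
    return best


def _leiden_once(net: Network, cfg: QualityConfig, rng: np.random.Generator) -> Partition:
    g, order = _as_graph(net)

    memb = np.arange(g.n)
    node_map = np.arange(g.n)  # original node -> current aggregated node
    history: list[float] = []
    passes = 0

    while passes < cfg.max_passes:
        _local_move(g, memb, cfg, rng)
        passes += 1
        history.append(_quality_value(g, memb, cfg))
        if len(np.unique(memb)) == g.n:
            break
        refined = _refine(g, memb, cfg, rng)
        if len(np.unique(refined)) == g.n:
            # refinement kept everything singleton; aggregation on the
            # unrefined partition would lose the connectivity guarantee,
            # and local moving is at a fixed point — stop.
            break
        g, memb, step_map = _aggregate(g, refined, memb)
        node_map = step_map[node_map]

    raw = [int(memb[node_map[i]]) for i in range(len(order))]
    relabel: dict[int, int] = {}
    for c in raw:
        if c not in relabel:
            relabel[c] = len(relabel)
    membership = {gene: relabel[c] for gene, c in zip(order, raw)}
    return Partition(
        membership=membership,
        quality=history[-1] if history else 0.0,
        n_passes=passes,
        quality_history=history,
    )


# ---------------------------------------------------------------------------
# per-community gene / variant / case statistics
# ---------------------------------------------------------------------------


def community_case_stats(partition: Mapping[str, int], qv) -> "pd.DataFrame":
    """Per-community counts of genes, qualifying variants and carrier cases.

    A case counts toward every community that contains at least one gene in
    which it carries a qualifying variant, so cases may be counted in several
    communities; the percentage denominator is the number of distinct cases
    across the whole network.

    Parameters
    ----------
    partition
        gene -> community label covering every network gene.
    qv
        Qualifying-variant table with columns ``gene`` and ``carriers``
        (each a set/frozenset of case identifiers).
    """
    import pandas as pd

    missing = sorted(set(qv["gene"]) - set(partition))
    if missing:
        raise ValueError(f"qualifying-variant gene(s) not in partition: {missing[:5]}")
    labels = sorted(set(partition.values()))
    genes_of = {c: set() for c in labels}
    for gene, c in partition.items():
        genes_of[c].add(gene)
    cases_of = {c: set() for c in labels}
    variants_of = {c: 0 for c in labels}
    all_cases: set = set()
    for row in qv.itertuples(index=False):
        c = partition[row.gene]
        cases_of[c].update(row.carriers)
        variants_of[c] += 1
        all_cases.update(row.carriers)
    denom = len(all_cases)
    rows = []
    for c in labels:
        n_cases = len(cases_of[c])
        rows.append(
            {
                "community": c,
                "n_genes": len(genes_of[c]),
                "n_variants": variants_of[c],
                "n_cases": n_cases,
                "pct_of_network_cases": round(100.0 * n_cases / denom, 1) if denom else 0.0,
            }
        )
    return pd.DataFrame(rows)
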