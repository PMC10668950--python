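"""Independent reference implementations used to check the package.

Everything here is deliberately brute-force / first-principles and shares no
code path with nsnet: exact hypergeometric tail by rational summation,
Benjamini-Hochberg by the literal step-up rule, modularity maximisation by
exhaustive enumeration of set partitions.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_upper_exact(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exact rational summation of the mass function."""
    total = Fraction(0)
    denom = comb(N, n)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return float(total)


def bh_stepup(p):
    """Literal BH step-up: sort, multiply by m/rank, enforce monotone minima."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def set_partitions(items):
    """All set partitions of a sequence (Bell(n) of them)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity_of(edges, nodes, blocks, gamma=1.0):
    """Weighted modularity of a partition given as a list of node lists."""
    m = sum(w for _, _, w in edges)
    if m == 0:
        return 0.0
    block_of = {}
    for b, members in enumerate(blocks):
        for v in members:
            block_of[v] = b
    strength = {v: 0.0 for v in nodes}
    w_in = [0.0] * len(blocks)
    for a, b, w in edges:
        strength[a] += w
        strength[b] += w
        if block_of[a] == block_of[b]:
            w_in[block_of[a]] += w
    s_c = [0.0] * len(blocks)
    for v in nodes:
        s_c[block_of[v]] += strength[v]
    return sum(w_in[c] / m - gamma * (s_c[c] / (2 * m)) ** 2 for c in range(len(blocks)))


def best_partition_bruteforce(edges, nodes, gamma=1.0):
    """Maximum-modularity partition by exhaustive search; returns (Q, blocks)."""
    best_q, best_blocks = -np.inf, None
    for blocks in set_partitions(nodes):
        q = modularity_of(edges, nodes, blocks, gamma)
        if q > best_q:
            best_q, best_blocks = q, blocks
    return best_q, best_blocks


def random_graph_edges(rng, n, p=0.5):
    """Unweighted Erdos-Renyi edge list on node labels n0..n{n-1}."""
    nodes = [f"n{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j], 1.0)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return nodes, edges
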