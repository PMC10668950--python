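"""Overrepresentation analysis of network communities against gene sets.

For each (community, pathway) pair with a non-empty overlap the module
reports the one-sided hypergeometric p-value P(X >= k), the fold enrichment

    fold = (k / n) / (K / N)

(the fraction of community genes in the set over the fraction of universe
genes in the set), and a Benjamini-Hochberg adjusted p-value computed within
each community's family of tested sets.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes in ``n`` draws without replacement from a universe of
    ``N`` objects of which ``K`` are successes.
    """
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N); undefined (NaN) when K == 0."""
    if n <= 0:
        raise ValueError("community size n must be positive")
    if K == 0:
        return float("nan")
    return (k / n) / (K / N)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {ln[:80]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


# ---------------------------------------------------------------------------
# community enrichment
# ---------------------------------------------------------------------------


def enrich_communities(
    partition: Mapping[str, int],
    gene_sets: Mapping[str, set[str]],
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ORA of every community against every gene set.

    Parameters
    ----------
    partition
        gene -> community label.
    gene_sets
        pathway name -> gene set (e.g. from :func:`read_gmt`).
    universe
        Background gene universe. Defaults to the union of all genes in the
        annotation collection; every community gene must be contained in it.
    alpha
        Stored threshold for the ``significant`` flag on adjusted p-values.

    Returns one row per (community, set) with overlap k >= 1; BH adjustment
    is applied within each community's family; sorted by community then
    adjusted p.
    """
    if universe is None:
        universe = set().union(*gene_sets.values()) if gene_sets else set()
    community_genes: dict[int, set[str]] = {}
    for gene, c in partition.items():
        community_genes.setdefault(c, set()).add(gene)
    stray = set(partition) - universe
    if stray:
        raise ValueError(
            f"community gene(s) absent from universe: {sorted(stray)[:5]} "
            "(choose a universe covering all community genes)"
        )
    N = len(universe)
    rows = []
    for c in sorted(community_genes):
        comm = community_genes[c]
        n = len(comm)
        family = []
        for name, members in gene_sets.items():
            members_u = members & universe
            K = len(members_u)
            k = len(comm & members_u)
            if k == 0:
                continue
            family.append(
                {
                    "community": c,
                    "set_name": name,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "p": hypergeom_upper(k, K, n, N),
                    "fold": fold_enrichment(k, n, K, N),
                }
            )
        if not family:
            logger.warning("community %s overlaps no gene set", c)
            continue
        padj = bh_adjust([r["p"] for r in family])
        for r, q in zip(family, padj):
            r["p_adj"] = float(q)
            r["significant"] = bool(q < alpha)
        family.sort(key=lambda r: (r["p_adj"], r["p"], r["set_name"]))
        rows.extend(family)
    return pd.DataFrame(
        rows,
        columns=["community", "set_name", "k", "n", "K", "N", "p", "fold", "p_adj", "significant"],
    )


def top_set_per_community(enrichment: pd.DataFrame) -> dict[int, str]:
    """Best-ranked (smallest adjusted p) set for each community."""
    out: dict[int, str] = {}
    for c, sub in enrichment.groupby("community"):
        out[int(c)] = sub.iloc[0]["set_name"]
    return out
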