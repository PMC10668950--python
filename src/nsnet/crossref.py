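"""Cross-referencing network genes against independent evidence sources.

Three sources, each with its own qualification rule:

* de novo SNVs: qualify with population MAF < 0.001 and a damaging in-silico
  label (SIFT deleterious OR PolyPhen probably/possibly damaging);
* de novo CNVs: qualify when flagged de novo and detected by >= 2 calling
  algorithms; a gene is hit when its interval overlaps the CNV by >= 1 bp
  (closed 1-based intervals, a touching endpoint counts);
* curated category lists: genes in the strongest evidence categories
  (score 1 or 2, or the syndromic flag; "2S" satisfies both).

Evidence is tallied per gene (three boolean flags plus their union) and per
community.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

DAMAGING_SIFT = {"deleterious"}
DAMAGING_POLYPHEN = {"probably_damaging", "possibly_damaging"}


def filter_denovo(records: pd.DataFrame, maf_max: float = 0.001) -> set[str]:
    """Genes with a qualifying de novo SNV.

    ``records`` columns: gene, maf, sift, polyphen. Qualify iff
    maf < maf_max AND (sift deleterious OR polyphen damaging). Records with
    both labels missing never qualify (logged).
    """
    out: set[str] = set()
    for r in records.itertuples(index=False):
        sift = str(r.sift).strip().lower() if pd.notna(r.sift) else ""
        poly = str(r.polyphen).strip().lower() if pd.notna(r.polyphen) else ""
        if not sift and not poly:
            logger.warning("de novo record for %s has no SIFT/PolyPhen label; skipped", r.gene)
            continue
        damaging = sift in DAMAGING_SIFT or poly in DAMAGING_POLYPHEN
        if float(r.maf) < maf_max and damaging:
            out.add(str(r.gene))
    return out


def _intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    # closed 1-based intervals; a touching endpoint is a 1-bp overlap
    return a_start <= b_end and b_start <= a_end


def filter_cnvs(
    records: pd.DataFrame, gene_intervals: pd.DataFrame
) -> tuple[pd.DataFrame, set[str]]:
    """Qualifying CNVs (de novo, detected by >= 2 algorithms) and hit genes.

    ``records`` columns: chrom, start, end, de_novo, n_algorithms.
    ``gene_intervals`` columns: gene, chrom, start, end (1-based inclusive).
    Malformed intervals (start > end) are rejected row-wise with a log entry.
    """
    ok_rows = []
    for r in records.itertuples(index=False):
        if int(r.start) > int(r.end):
            logger.warning("CNV %s:%s-%s rejected: start > end", r.chrom, r.start, r.end)
            continue
        if bool(r.de_novo) and int(r.n_algorithms) >= 2:
            ok_rows.append(r._asdict() if hasattr(r, "_asdict") else dict(r._asdict()))
    qualifying = pd.DataFrame(ok_rows, columns=list(records.columns))
    hit: set[str] = set()
    for cnv in qualifying.itertuples(index=False):
        for g in gene_intervals.itertuples(index=False):
            if str(g.chrom) == str(cnv.chrom) and _intervals_overlap(
                int(cnv.start), int(cnv.end), int(g.start), int(g.end)
            ):
                hit.add(str(g.gene))
    return qualifying, hit


_CATEGORY_RE = re.compile(r"^\s*(?P<score>[123])?\s*(?P<synd>S)?\s*$", re.IGNORECASE)


def parse_category(raw: str) -> tuple[int | None, bool]:
    """Parse a category string like "1", "2", "S", "2S" -> (score, syndromic)."""
    m = _CATEGORY_RE.match(str(raw))
    if not m or (m.group("score") is None and m.group("synd") is None):
        raise ValueError(f"unparseable category {raw!r}")
    score = int(m.group("score")) if m.group("score") else None
    return score, m.group("synd") is not None


def select_categories(entries: pd.DataFrame) -> set[str]:
    """Genes in the strongest categories: score 1 or 2, or syndromic.

    ``entries`` columns: gene, category. Unparseable categories are skipped
    with a log entry.
    """
    out: set[str] = set()
    for r in entries.itertuples(index=False):
        try:
            score, syndromic = parse_category(r.category)
        except ValueError:
            logger.warning("category %r for %s skipped", r.category, r.gene)
            continue
        if score in (1, 2) or syndromic:
            out.add(str(r.gene))
    return out


def tally_evidence(
    network_genes: Iterable[str],
    partition: Mapping[str, int],
    denovo_genes: set[str],
    cnv_genes: set[str],
    category_genes: set[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene evidence flags and per-community counts.

    Gene symbols are matched case-insensitively. Returns
    ``(per_gene, per_community)``; per-community rows carry counts for each
    source, the union (a gene with several sources counted once) and the
    community size.
    """
    dn = {g.lower() for g in denovo_genes}
    cn = {g.lower() for g in cnv_genes}
    cat = {g.lower() for g in category_genes}
    rows = []
    for gene in sorted(set(network_genes)):
        gl = gene.lower()
        flags = (gl in dn, gl in cn, gl in cat)
        rows.append(
            {
                "gene": gene,
                "community": partition.get(gene),
                "denovo_snv": flags[0],
                "denovo_cnv": flags[1],
                "category": flags[2],
                "any_evidence": any(flags),
            }
        )
    per_gene = pd.DataFrame(
        rows, columns=["gene", "community", "denovo_snv", "denovo_cnv", "category", "any_evidence"]
    )
    per_comm = (
        per_gene.groupby("community", dropna=False)
        .agg(
            n_genes=("gene", "size"),
            n_denovo_snv=("denovo_snv", "sum"),
            n_denovo_cnv=("denovo_cnv", "sum"),
            n_category=("category", "sum"),
            n_any=("any_evidence", "sum"),
        )
        .reset_index()
    )
    return per_gene, per_comm


# ---------------------------------------------------------------------------
# table readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    df.columns = [c.lower() for c in df.columns]
    if not required.issubset(df.columns):
        raise ValueError(f"{path} must have columns {sorted(required)}")
    return df


def read_denovo_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, {"gene", "maf", "sift", "polyphen"})


def read_cnv_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, {"chrom", "start", "end", "de_novo", "n_algorithms"})


def read_category_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, {"gene", "category"})


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, {"gene", "chrom", "start", "end"})
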