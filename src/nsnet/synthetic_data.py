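"""Synthetic inputs with planted ground truth for the whole pipeline.

Every file the pipeline consumes can be generated here: a cohort VCF with
per-genotype DP/GQ/AD and per-site VQSLOD plus gene/consequence annotation,
a gnomAD-like control allele-frequency table, a candidate gene list, a
STRING-like confidence-weighted PPI edge table, GMT pathway sets, a part_of
anatomy DAG with gene x region expression calls, and de novo SNV / CNV /
category tables for cross-dataset validation.

The generator plants recoverable structure at every stage and records it in
:class:`PlantedTruth`:

* community structure — a planted-partition (stochastic block model) graph
  with within-community edge probability ``p_in`` and between probability
  ``p_out``; within-community confidences are drawn higher than between;
* rare-LoF burden — a known set of sites passes every QC/frequency/LoF/
  candidate filter, with carriers recorded per gene, while contaminant
  sites are each planted to fail exactly one named filter;
* pathway enrichment — one planted gene set per community drawn with
  ``pathway_purity`` from that community, among uniform decoy sets;
* regional expression signal — genes of each community are present-called
  in that community's planted brain region with their odds multiplied by
  ``region_signal_strength``.

Determinism: a single global integer seed; each stage draws from a
generator seeded with ``[seed, stage_index]``, so outputs are byte-identical
for a fixed :class:`SimConfig` regardless of stage call order.

Gene symbols are synthetic (G0001, ...), so nothing depends on real
annotation. The simulation does not attempt realistic linkage, mutation-rate
or inheritance modelling; it exists to make planted signal recoverable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .enrichment import write_gmt
from .brain_expression import AnatomyDAG, write_calls
from .variant_filter import LOF_CLASSES, variant_key

_STAGE_PPI, _STAGE_COHORT, _STAGE_GMT, _STAGE_ONTO, _STAGE_XREF = range(5)

_LOF_CHOICES = sorted(LOF_CLASSES)
# stop gains dominate, echoing the usual LoF class mix in exome studies
_LOF_WEIGHTS = {"stop_gain": 0.49, "frameshift": 0.25, "splice_acceptor": 0.10,
                "splice_donor": 0.10, "start_lost": 0.06}

GENE_SPAN = 50_000
GENE_STRIDE = 100_000


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort and its annotation universe."""

    seed: int = 0
    n_genes: int = 60
    n_communities: int = 3
    p_in: float = 0.3
    p_out: float = 0.02
    n_cases: int = 400
    n_controls_freq_table: int = 60146
    lof_rate_per_gene: float = 0.9
    background_variant_rate: float = 0.5
    frac_common_contaminant: float = 0.3
    n_pathways: int = 12
    pathway_purity: float = 0.9
    n_regions: int = 8
    region_signal_strength: float = 8.0

    def __post_init__(self):
        for name in ("p_in", "p_out", "lof_rate_per_gene", "background_variant_rate",
                     "frac_common_contaminant", "pathway_purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")
        if self.n_genes < self.n_communities or self.n_communities < 1:
            raise ValueError("need n_genes >= n_communities >= 1")
        if self.n_regions < 2:
            raise ValueError("need n_regions >= 2")
        if self.n_pathways < self.n_communities:
            raise ValueError("need n_pathways >= n_communities (one planted set each)")
        if self.region_signal_strength <= 0:
            raise ValueError("region_signal_strength must be > 0")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class PlantedTruth:
    """Ground truth recorded while generating the synthetic inputs."""

    community_of_gene: dict[str, int] = field(default_factory=dict)
    enriched_pathway_of_community: dict[int, str] = field(default_factory=dict)
    enriched_region_of_community: dict[int, str] = field(default_factory=dict)
    carrier_cases_by_gene: dict[str, set[str]] = field(default_factory=dict)
    qualifying_keys: set[str] = field(default_factory=set)
    contaminant_filter_of_key: dict[str, str] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)
    denovo_genes: set[str] = field(default_factory=set)
    cnv_genes: set[str] = field(default_factory=set)
    category_genes: set[str] = field(default_factory=set)

    @property
    def qualifying_genes(self) -> set[str]:
        return {g for g, cases in self.carrier_cases_by_gene.items() if cases}

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, set):
                d[k] = sorted(v)
            elif isinstance(v, dict):
                d[k] = {str(kk): (sorted(vv) if isinstance(vv, set) else vv) for kk, vv in v.items()}
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def gene_symbols(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def gene_intervals(genes: Iterable[str]) -> pd.DataFrame:
    """Deterministic non-overlapping 1-based intervals, one gene per 100 kb."""
    rows = [
        {"gene": g, "chrom": "1", "start": i * GENE_STRIDE + 1,
         "end": i * GENE_STRIDE + GENE_SPAN}
        for i, g in enumerate(genes)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------


def simulate_ppi(cfg: SimConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Planted-partition PPI edge table.

    Genes are assigned to communities round-robin; each within-community
    pair is an edge with probability ``p_in`` (confidence U(0.6, 1.0)) and
    each between pair with probability ``p_out`` (confidence U(0.4, 0.7)).
    Undirected, deduplicated, no self-edges.
    """
    rng = cfg.rng(_STAGE_PPI)
    genes = gene_symbols(cfg.n_genes)
    truth = PlantedTruth(genes=genes)
    truth.community_of_gene = {g: i % cfg.n_communities for i, g in enumerate(genes)}
    rows = []
    for i in range(cfg.n_genes):
        for j in range(i + 1, cfg.n_genes):
            same = truth.community_of_gene[genes[i]] == truth.community_of_gene[genes[j]]
            p = cfg.p_in if same else cfg.p_out
            if rng.random() < p:
                lo, hi = (0.6, 1.0) if same else (0.4, 0.7)
                rows.append(
                    {"gene_a": genes[i], "gene_b": genes[j],
                     "confidence": round(float(rng.uniform(lo, hi)), 3)}
                )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"]), truth


# ---------------------------------------------------------------------------
# cohort VCF + control frequencies
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    samples: list[str]
    sites: list[dict]            # per-site metadata + genotype arrays
    control_af: pd.DataFrame     # chrom pos ref alt af
    candidate_genes: list[str]


def _random_snv(rng, pos_pool: set[int], start: int, end: int) -> tuple[int, str, str]:
    while True:
        pos = int(rng.integers(start, end + 1))
        if pos not in pos_pool:
            pos_pool.add(pos)
            break
    bases = ["A", "C", "G", "T"]
    ref = bases[rng.integers(4)]
    alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
    return pos, ref, alt


def _clean_genotypes(rng, n: int, carriers_idx: np.ndarray) -> dict:
    gt = np.zeros(n, dtype=np.int64)
    dp = np.full(n, 30, dtype=np.int64)
    gq = np.full(n, 80, dtype=np.int64)
    ad_ref = dp.copy()
    ad_alt = np.zeros(n, dtype=np.int64)
    for c in carriers_idx:
        gt[c] = 1
        d = int(rng.integers(20, 61))
        frac = rng.uniform(0.35, 0.65)
        alt = max(1, int(round(d * frac)))
        dp[c], gq[c] = d, int(rng.integers(60, 100))
        ad_alt[c], ad_ref[c] = alt, d - alt
    return {"gt": gt, "dp": dp, "gq": gq, "ad_ref": ad_ref, "ad_alt": ad_alt}


def _pick_lof(rng) -> str:
    names = sorted(_LOF_WEIGHTS)
    p = np.array([_LOF_WEIGHTS[n] for n in names])
    return str(rng.choice(names, p=p / p.sum()))


def simulate_cohort(cfg: SimConfig, truth: PlantedTruth) -> SimulatedCohort:
    """Cohort VCF content plus control AF table, with planted pass/fail sites.

    Qualifying sites pass every filter and their carriers are recorded in
    ``truth.carrier_cases_by_gene``. Contaminant sites each fail exactly one
    named filter: vqslod, missingness, dp, gq, allele_balance, frequency,
    consequence (non-LoF) or offlist (gene not on the candidate list) —
    including the boundary cases DP = 8, GQ = 20, allele balance = 0.2,
    control AF exactly 0.1%.
    """
    rng = cfg.rng(_STAGE_COHORT)
    n = cfg.n_cases
    samples = [f"CASE{i + 1:05d}" for i in range(n)]
    intervals = gene_intervals(truth.genes).set_index("gene")
    pos_pool: set[int] = set()
    sites: list[dict] = []
    af_rows: list[dict] = []
    truth.carrier_cases_by_gene = {g: set() for g in truth.genes}

    def add_site(gene: str, csq: str, vqslod: float, genos: dict,
                 af: float | None, start: int, end: int, kind: str | None) -> str:
        pos, ref, alt = _random_snv(rng, pos_pool, start, end)
        key = variant_key("1", pos, ref, alt)
        sites.append({"chrom": "1", "pos": pos, "ref": ref, "alt": alt,
                      "vqslod": round(vqslod, 2), "gene": gene, "csq": csq, **genos})
        if af is not None:
            af_rows.append({"chrom": "1", "pos": pos, "ref": ref, "alt": alt, "af": af})
        if kind is not None:
            truth.contaminant_filter_of_key[key] = kind
        return key

    # --- qualifying sites -------------------------------------------------
    for gene in truth.genes:
        if rng.random() >= cfg.lof_rate_per_gene:
            continue
        iv = intervals.loc[gene]
        n_var = 1 + int(rng.poisson(0.7))
        for _ in range(n_var):
            n_carriers = 1 + int(rng.binomial(2, 0.05))
            carriers_idx = rng.choice(n, size=min(n_carriers, n), replace=False)
            genos = _clean_genotypes(rng, n, carriers_idx)
            af = None if rng.random() < 0.5 else round(float(rng.uniform(0, 0.0008)), 6)
            key = add_site(gene, _pick_lof(rng), max(float(rng.normal(5, 2)), -1.0),
                           genos, af, int(iv.start), int(iv.end), None)
            truth.qualifying_keys.add(key)
            truth.carrier_cases_by_gene[gene].update(samples[int(i)] for i in carriers_idx)

    n_qual = len(truth.qualifying_keys)

    def random_gene():
        return truth.genes[int(rng.integers(len(truth.genes)))]

    def contaminant(kind: str, gene: str | None = None):
        gene = gene or random_gene()
        iv = intervals.loc[gene]
        carriers_idx = rng.choice(n, size=1, replace=False)
        genos = _clean_genotypes(rng, n, carriers_idx)
        vqslod = max(float(rng.normal(5, 2)), -1.0)
        csq = _pick_lof(rng)
        af: float | None = None
        c = int(carriers_idx[0])
        if kind == "vqslod":
            vqslod = float(rng.uniform(-6.0, -1.6))
        elif kind == "missingness":
            n_miss = max(int(np.ceil(0.10 * n)), 1)
            miss = rng.choice(np.setdiff1d(np.arange(n), carriers_idx),
                              size=min(n_miss, n - 1), replace=False)
            genos["gt"][miss] = -1
        elif kind == "dp":
            genos["dp"][c] = 8  # boundary: DP > 8 required
        elif kind == "gq":
            genos["gq"][c] = 20  # boundary: GQ > 20 required
        elif kind == "allele_balance":
            genos["dp"][c] = 40
            genos["ad_alt"][c] = 8   # 8/40 = 0.2, boundary fails
            genos["ad_ref"][c] = 32
        elif kind == "frequency":
            af = round(float(rng.uniform(0.001, 0.2)), 6)
        elif kind == "frequency_boundary":
            af, kind = 0.001, "frequency"
        elif kind == "consequence":
            csq = "other"
        elif kind == "offlist":
            gene = f"GX_OFF{len(truth.contaminant_filter_of_key):03d}"
            iv = pd.Series({"start": (len(truth.genes) + 5) * GENE_STRIDE + 1,
                            "end": (len(truth.genes) + 6) * GENE_STRIDE})
        else:  # pragma: no cover
            raise ValueError(kind)
        add_site(gene, csq, vqslod, genos, af, int(iv.start), int(iv.end), kind)

    # one contaminant per failure mode, always present
    for kind in ("vqslod", "missingness", "dp", "gq", "allele_balance",
                 "frequency_boundary", "consequence", "offlist"):
        contaminant(kind)
    # common-variant contamination at the configured fraction of sites
    for _ in range(int(round(cfg.frac_common_contaminant * n_qual))):
        contaminant("frequency")
    # background non-LoF sites that pass QC but are not LoF
    for gene in truth.genes:
        if rng.random() < cfg.background_variant_rate:
            contaminant("consequence", gene=gene)

    # a sprinkle of control-only table rows (never in the cohort VCF)
    for _ in range(20):
        pos, ref, alt = _random_snv(rng, pos_pool, 1, len(truth.genes) * GENE_STRIDE)
        af_rows.append({"chrom": "1", "pos": pos, "ref": ref, "alt": alt,
                        "af": round(float(rng.uniform(0, 0.05)), 6)})

    sites.sort(key=lambda s: (s["chrom"], s["pos"]))
    control_af = pd.DataFrame(af_rows, columns=["chrom", "pos", "ref", "alt", "af"])
    control_af = control_af.sort_values(["chrom", "pos"], ignore_index=True)
    return SimulatedCohort(samples, sites, control_af, list(truth.genes))


def write_vcf(cohort: SimulatedCohort, path: str | Path) -> None:
    """Write the simulated cohort as VCFv4.2 (single ALT per record)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##INFO=<ID=VQSLOD,Number=1,Type=Float,Description="Variant quality score log-odds">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.samples) + "\n")
        gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for s in cohort.sites:
            info = f"VQSLOD={s['vqslod']};GENE={s['gene']};CSQ={s['csq']}"
            cols = [s["chrom"], str(s["pos"]), ".", s["ref"], s["alt"], ".", "PASS",
                    info, "GT:DP:GQ:AD"]
            for i in range(len(cohort.samples)):
                cols.append(
                    f"{gt_str[int(s['gt'][i])]}:{s['dp'][i]}:{s['gq'][i]}:"
                    f"{s['ad_ref'][i]},{s['ad_alt'][i]}"
                )
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# pathway sets
# ---------------------------------------------------------------------------


def simulate_annotations(truth: PlantedTruth, cfg: SimConfig) -> dict[str, set[str]]:
    """GMT gene sets: one planted set per community plus uniform decoys.

    The planted set for community c draws a ``pathway_purity`` fraction of
    its members from community c and the rest uniformly from other genes;
    every gene is guaranteed annotation in at least one set so the
    union-universe covers the network.
    """
    rng = cfg.rng(_STAGE_GMT)
    by_comm: dict[int, list[str]] = {}
    for g, c in truth.community_of_gene.items():
        by_comm.setdefault(c, []).append(g)
    sets: dict[str, set[str]] = {}
    for c in sorted(by_comm):
        comm = sorted(by_comm[c])
        others = sorted(set(truth.genes) - set(comm))
        size = max(4, min(15, len(comm)))
        n_pure = min(len(comm), int(round(cfg.pathway_purity * size)))
        members = set(rng.choice(comm, size=n_pure, replace=False))
        n_noise = min(len(others), size - n_pure)
        if n_noise > 0:
            members |= set(rng.choice(others, size=n_noise, replace=False))
        name = f"PW_PLANTED_C{c}"
        sets[name] = members
        truth.enriched_pathway_of_community[c] = name
    for d in range(cfg.n_pathways - len(by_comm)):
        size = int(rng.integers(8, 21))
        sets[f"PW_DECOY_{d:02d}"] = set(
            rng.choice(truth.genes, size=min(size, len(truth.genes)), replace=False)
        )
    covered = set().union(*sets.values())
    decoys = [k for k in sets if k.startswith("PW_DECOY")]
    uncovered = sorted(set(truth.genes) - covered)
    if uncovered and not decoys:
        sets["PW_UNANNOTATED"] = set()
        decoys = ["PW_UNANNOTATED"]
    for i, g in enumerate(uncovered):
        sets[decoys[i % len(decoys)]].add(g)
    return sets


# ---------------------------------------------------------------------------
# anatomy DAG + expression calls
# ---------------------------------------------------------------------------


def simulate_ontology_and_calls(
    truth: PlantedTruth, cfg: SimConfig
) -> tuple[AnatomyDAG, set[tuple[str, str]]]:
    """A brain part_of DAG plus gene x region present calls.

    All regions are direct children of the root "brain" term: under
    true-path propagation any intermediate grouping term would inherit the
    signal of a planted region beneath it, making "which region is
    enriched" ill-posed at the planted granularity. Genes of community c
    are called present in the community's planted region with baseline odds
    multiplied by ``region_signal_strength`` and divided by it elsewhere
    (regional specificity; strength 1 plants no association).
    """
    rng = cfg.rng(_STAGE_ONTO)
    root = "BR:0000"
    leaves = [f"BR:{100 + i:04d}" for i in range(cfg.n_regions)]
    dag = AnatomyDAG([(leaf, root) for leaf in leaves])
    comms = sorted(set(truth.community_of_gene.values()))
    for i, c in enumerate(comms):
        truth.enriched_region_of_community[c] = leaves[i % len(leaves)]
    # regional specificity: community genes concentrate their expression in
    # the planted region — odds multiplied by the signal strength there and
    # divided by it elsewhere (strength 1 leaves the baseline untouched)
    base = 0.3
    base_odds = base / (1.0 - base)
    s = cfg.region_signal_strength
    boosted = base_odds * s / (1.0 + base_odds * s)
    suppressed = (base_odds / s) / (1.0 + base_odds / s)
    calls: set[tuple[str, str]] = set()
    for g in truth.genes:
        planted = truth.enriched_region_of_community[truth.community_of_gene[g]]
        for leaf in leaves:
            p = boosted if leaf == planted else suppressed
            if rng.random() < p:
                calls.add((g, leaf))
    return dag, calls


# ---------------------------------------------------------------------------
# cross-reference evidence tables
# ---------------------------------------------------------------------------


def simulate_crossref(
    truth: PlantedTruth, cfg: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """De novo SNV, CNV and category tables with planted pass/fail records.

    Per evidence source roughly two genes per community qualify; failing
    records are planted for every rule (MAF at/above the 0.001 bound,
    benign labels, single-algorithm CNVs, inherited CNVs, weak categories).
    """
    rng = cfg.rng(_STAGE_XREF)
    by_comm: dict[int, list[str]] = {}
    for g, c in truth.community_of_gene.items():
        by_comm.setdefault(c, []).append(g)
    intervals = gene_intervals(truth.genes).set_index("gene")

    def pick(comm: int, k: int) -> list[str]:
        pool = sorted(by_comm[comm])
        k = min(k, len(pool))
        return [str(x) for x in rng.choice(pool, size=k, replace=False)]

    dn_rows, cnv_rows, cat_rows = [], [], []
    for c in sorted(by_comm):
        for g in pick(c, 2):
            label = ("deleterious", "benign") if rng.random() < 0.5 else ("tolerated", "probably_damaging")
            dn_rows.append({"gene": g, "maf": round(float(rng.uniform(0, 0.0008)), 6),
                            "sift": label[0], "polyphen": label[1]})
            truth.denovo_genes.add(g)
        for g in pick(c, 2):
            iv = intervals.loc[g]
            cnv_rows.append({"chrom": "1", "start": int(iv.start) - 1000,
                             "end": int(iv.end) + 1000, "de_novo": True,
                             "n_algorithms": int(rng.integers(2, 4))})
            truth.cnv_genes.add(g)
        for g, cat in zip(pick(c, 2), ["1", "2", "S", "2S"]):
            cat_rows.append({"gene": g, "category": cat})
            truth.category_genes.add(g)
    # planted failures
    fail_genes = [str(x) for x in rng.choice(truth.genes, size=6, replace=False)]
    dn_rows.append({"gene": fail_genes[0], "maf": 0.001, "sift": "deleterious",
                    "polyphen": "probably_damaging"})     # MAF boundary
    dn_rows.append({"gene": fail_genes[1], "maf": 0.0001, "sift": "tolerated",
                    "polyphen": "benign"})                # benign labels
    iv = intervals.loc[fail_genes[2]]
    cnv_rows.append({"chrom": "1", "start": int(iv.start), "end": int(iv.end),
                     "de_novo": True, "n_algorithms": 1})   # single algorithm
    iv = intervals.loc[fail_genes[3]]
    cnv_rows.append({"chrom": "1", "start": int(iv.start), "end": int(iv.end),
                     "de_novo": False, "n_algorithms": 3})  # inherited
    cat_rows.append({"gene": fail_genes[4], "category": "3"})
    cat_rows.append({"gene": fail_genes[5], "category": "?"})  # unparseable, skipped
    denovo = pd.DataFrame(dn_rows, columns=["gene", "maf", "sift", "polyphen"])
    cnvs = pd.DataFrame(cnv_rows, columns=["chrom", "start", "end", "de_novo", "n_algorithms"])
    cats = pd.DataFrame(cat_rows, columns=["gene", "category"])
    return denovo, cnvs, cats


# ---------------------------------------------------------------------------
# one-call writer
# ---------------------------------------------------------------------------

FILENAMES = {
    "vcf": "cohort.vcf",
    "control_af": "control_af.tsv",
    "genes": "candidate_genes.txt",
    "edges": "ppi_edges.tsv",
    "gmt": "pathways.gmt",
    "anatomy": "anatomy.tsv",
    "calls": "expression_calls.tsv",
    "denovo": "denovo_snv.tsv",
    "cnv": "cnv.tsv",
    "categories": "categories.tsv",
    "gene_intervals": "gene_intervals.tsv",
    "truth": "planted_truth.json",
}


def simulate_all(cfg: SimConfig, outdir: str | Path) -> PlantedTruth:
    """Generate and write every pipeline input into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges, truth = simulate_ppi(cfg)
    edges.to_csv(outdir / FILENAMES["edges"], sep="\t", index=False)
    cohort = simulate_cohort(cfg, truth)
    write_vcf(cohort, outdir / FILENAMES["vcf"])
    cohort.control_af.to_csv(outdir / FILENAMES["control_af"], sep="\t", index=False)
    (outdir / FILENAMES["genes"]).write_text("\n".join(truth.genes) + "\n")
    write_gmt(simulate_annotations(truth, cfg), outdir / FILENAMES["gmt"])
    dag, calls = simulate_ontology_and_calls(truth, cfg)
    dag.to_tsv(outdir / FILENAMES["anatomy"])
    write_calls(calls, outdir / FILENAMES["calls"])
    denovo, cnvs, cats = simulate_crossref(truth, cfg)
    denovo.to_csv(outdir / FILENAMES["denovo"], sep="\t", index=False)
    cnvs.to_csv(outdir / FILENAMES["cnv"], sep="\t", index=False)
    cats.to_csv(outdir / FILENAMES["categories"], sep="\t", index=False)
    gene_intervals(truth.genes).to_csv(outdir / FILENAMES["gene_intervals"], sep="\t", index=False)
    truth.to_json(outdir / FILENAMES["truth"])
    return truth
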