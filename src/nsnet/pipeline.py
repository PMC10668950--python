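"""End-to-end orchestration: simulate -> filter -> network -> communities ->
enrich -> express -> crossref -> report.

A single :class:`PipelineConfig` (YAML-serialisable) drives all stages; the
effective configuration and its hash are written next to the outputs, every
output TSV starts with a ``# config_hash=`` provenance line, and per-stage
log lines record counts in/out of every filter so headline numbers can be
audited. Outputs are byte-identical for a fixed config and seed (the
rendered heatmap image excluded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import brain_expression as bx
from . import crossref as xr
from . import enrichment as en
from . import leiden as ld
from . import ppi_network as nw
from . import synthetic_data as sd
from . import variant_filter as vf

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "nsnet_out"
    seed: int = 0
    simulate: bool = True
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    # input paths; when simulate=True they default to the simulated files
    vcf: str | None = None
    control_af: str | None = None
    genes: str | None = None
    edges: str | None = None
    gmt: str | None = None
    anatomy: str | None = None
    calls: str | None = None
    denovo: str | None = None
    cnv: str | None = None
    categories: str | None = None
    gene_intervals: str | None = None
    # stage parameters
    qc: vf.QCThresholds = field(default_factory=vf.QCThresholds)
    confidence_min: float = nw.DEFAULT_CONFIDENCE_MIN
    quality: str = "modularity"
    resolution: float = 1.0
    theta: float = 0.01
    universe: str = "annotation"  # or "network"
    parent_child: str = "union"   # or "intersection"
    display_q: float = 0.05

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = sd.SimConfig(**self.sim)
        if isinstance(self.qc, dict):
            self.qc = vf.QCThresholds(**self.qc)
        if self.universe not in ("annotation", "network"):
            raise ValueError(f"universe must be 'annotation' or 'network', got {self.universe!r}")
        if self.simulate:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        # hash the scientific parameters only; where outputs land is not
        # part of what they contain
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the in-memory outputs.

    A stage failure raises ``RuntimeError`` naming the failing stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    (out / "effective_config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    results: dict = {"config_hash": h}

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s: start", name)
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return deco

    inputs = {k: getattr(config, k) for k in
              ("vcf", "control_af", "genes", "edges", "gmt", "anatomy", "calls",
               "denovo", "cnv", "categories", "gene_intervals")}

    @stage("simulate")
    def _():
        if not config.simulate:
            missing = [k for k, v in inputs.items() if v is None]
            if missing:
                raise FileNotFoundError(f"missing input path(s): {missing}")
            for k, v in inputs.items():
                if not Path(v).exists():
                    raise FileNotFoundError(f"input '{k}' not found: {v}")
            return
        indir = out / "inputs"
        results["truth"] = sd.simulate_all(config.sim, indir)
        name_of = dict(sd.FILENAMES)
        for k in inputs:
            inputs[k] = str(indir / name_of[k])

    @stage("filter")
    def _():
        calls = vf.read_cohort_vcf(inputs["vcf"])
        control = vf.read_control_af(inputs["control_af"])
        genes = vf.read_gene_list(inputs["genes"])
        qv = vf.run_filter_chain(calls, control, genes, config.qc)
        results["qv"] = qv
        results["n_cases"] = len(calls.samples)
        results["summary"] = vf.summarize_cohort(qv, len(calls.samples), len(genes))
        results["burden"] = vf.per_gene_burden(qv, len(calls.samples))
        vf.write_qualifying_table(qv, out / "qualifying_variants.tsv", f"config_hash={h}")
        _write_tsv(pd.DataFrame([dataclasses.asdict(results["summary"])]),
                   out / "cohort_summary.tsv", h)
        _write_tsv(results["burden"], out / "gene_burden.tsv", h)

    @stage("network")
    def _():
        if results["qv"].empty:
            logger.warning("no qualifying variants; skipping network-dependent stages")
            return
        edge_table = nw.read_edge_table(inputs["edges"])
        gene_set = set(results["qv"]["gene"])
        net = nw.build_network(edge_table, gene_set, config.confidence_min)
        results["network"] = net
        summ = nw.network_summary(net)
        results["network_summary"] = summ
        nw.write_edge_list(net, out / "network_edges.tsv")
        nw.write_graphml(net, out / "network.graphml")
        _write_tsv(summ["degree_table"], out / "degree_table.tsv", h)

    @stage("communities")
    def _():
        if "network" not in results or results["network"].n_nodes == 0:
            return
        qcfg = ld.QualityConfig(quality=config.quality, resolution=config.resolution,
                                theta=config.theta, seed=config.seed)
        part = ld.leiden(results["network"], qcfg)
        results["partition"] = part
        results["community_stats"] = ld.community_case_stats(part.membership, results["qv"])
        memb = pd.DataFrame(sorted(part.membership.items()), columns=["gene", "community"])
        _write_tsv(memb, out / "partition.tsv", h)
        _write_tsv(results["community_stats"], out / "community_stats.tsv", h)

    @stage("enrich")
    def _():
        if "partition" not in results:
            return
        sets = en.read_gmt(inputs["gmt"])
        memb = results["partition"].membership
        universe = None if config.universe == "annotation" else set(memb)
        enr = en.enrich_communities(memb, sets, universe=universe)
        results["enrichment"] = enr
        _write_tsv(enr, out / "pathway_enrichment.tsv", h)

    @stage("express")
    def _():
        if "partition" not in results:
            return
        dag = bx.AnatomyDAG.from_tsv(inputs["anatomy"])
        calls = bx.read_calls(inputs["calls"])
        comms = {c: set(genes) for c, genes in results["partition"].communities().items()}
        matrix = bx.region_enrichment(comms, dag, calls, variant=config.parent_child,
                                      display_q=None)
        results["region_matrix"] = matrix
        shown = matrix[(matrix < config.display_q).any(axis=1)]
        results["region_matrix_shown"] = shown
        _write_tsv(matrix.reset_index(), out / "region_enrichment_full.tsv", h)
        _write_tsv(shown.reset_index(), out / "region_enrichment.tsv", h)
        if len(shown) and shown.shape[1] >= 2:
            order, _link = bx.cluster_communities(shown)
            results["community_order"] = order
            bx.plot_heatmap(shown, out / "region_heatmap.png")

    @stage("crossref")
    def _():
        if "partition" not in results:
            return
        dn = xr.filter_denovo(xr.read_denovo_table(inputs["denovo"]))
        _, cnv_hits = xr.filter_cnvs(xr.read_cnv_table(inputs["cnv"]),
                                     xr.read_gene_intervals(inputs["gene_intervals"]))
        cats = xr.select_categories(xr.read_category_table(inputs["categories"]))
        per_gene, per_comm = xr.tally_evidence(
            results["partition"].membership.keys(), results["partition"].membership,
            dn, cnv_hits, cats)
        results["evidence_per_gene"] = per_gene
        results["evidence_per_community"] = per_comm
        _write_tsv(per_gene, out / "evidence_per_gene.tsv", h)
        _write_tsv(per_comm, out / "evidence_per_community.tsv", h)

    @stage("report")
    def _():
        results["report"] = make_report(results, out)
        (out / "report.md").write_text(results["report"])

    return results


def make_report(results: dict, outdir: Path) -> str:
    """Human-readable summary of counts, communities, top enrichments."""
    lines = [
        "# nsnet pipeline report",
        "",
        f"config hash: {results.get('config_hash', 'n/a')}",
        "",
    ]
    warn = []
    s = results.get("summary")
    if s is not None:
        if s.n_variants == 0:
            warn.append("no qualifying variants survived the filter chain")
        lines += [
            "## Qualifying ultra-rare LoF variants",
            f"- {s.n_variants} variants in {s.n_genes} genes "
            f"({s.pct_genes}% of the {s.n_candidate_genes}-gene candidate list)",
            f"- carried by {s.n_carrier_cases} cases ({s.pct_cases}% of {s.n_cohort} cases)",
            f"- {s.n_private} private variants; sharing histogram {s.sharing_histogram}",
            "",
        ]
    else:
        warn.append("filter stage output missing")
    ns = results.get("network_summary")
    if ns is not None:
        lines += [
            "## PPI network",
            f"- {ns['n_nodes']} nodes, {ns['n_edges']} edges, "
            f"average local clustering {ns['avg_clustering']:.3f}",
            "",
        ]
    part = results.get("partition")
    if part is not None:
        lines += [
            "## Communities",
            f"- {part.n_communities} communities; quality {part.quality:.4f} "
            f"after {part.n_passes} passes",
            "",
        ]
        cs = results.get("community_stats")
        if cs is not None:
            lines += [cs.to_string(index=False), ""]
    enr = results.get("enrichment")
    if enr is not None and len(enr):
        lines += ["## Top pathway per community"]
        for c, name in sorted(en.top_set_per_community(enr).items()):
            row = enr[(enr["community"] == c) & (enr["set_name"] == name)].iloc[0]
            lines.append(f"- community {c}: {name} "
                         f"(k={row.k}/{row.n}, fold={row.fold:.2f}, p_adj={row.p_adj:.2e})")
        lines.append("")
    shown = results.get("region_matrix_shown")
    if shown is not None:
        lines += [
            "## Brain-region expression enrichment",
            f"- {len(shown)} regions with Q below threshold "
            "(heatmap: region_heatmap.png)",
            "",
        ]
    ev = results.get("evidence_per_community")
    if ev is not None:
        lines += ["## Independent evidence per community", ev.to_string(index=False), ""]
    if warn:
        lines += ["## Warnings"] + [f"- {w}" for w in warn] + [""]
    return "\n".join(lines)
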