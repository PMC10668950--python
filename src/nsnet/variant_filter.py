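"""QC, population-frequency, LoF and candidate-gene filtering of a cohort VCF.

The filter chain reproduces a standard ultra-rare loss-of-function workflow
on whole-exome calls:

1. site/genotype quality control — VQSLOD >= -1.5, DP > 8, GQ > 20,
   allele balance > 0.2 on ALT-carrying genotypes, per-site missingness
   < 10% among cases;
2. population-frequency filtering against a large control allele-frequency
   table (gnomAD-like), keeping sites absent from the table or with
   MAF < 0.1%;
3. restriction to loss-of-function consequence classes (frameshift,
   stop gain, start lost, splice acceptor, splice donor);
4. restriction to a candidate gene list.

Site-level filters 2-4 commute; the chain yields a qualifying-variant table
(variant x gene x carrier cases) plus cohort-level summaries.

Boundary semantics are strict as printed: DP = 8 fails, GQ = 20 fails,
allele balance = 0.2 fails, VQSLOD = -1.5 passes, control MAF = 0.1% is
removed. A genotype with a required FORMAT field absent fails closed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: consequence classes counted as loss-of-function; anything else is "other"
LOF_CLASSES = frozenset(
    {"frameshift", "stop_gain", "start_lost", "splice_acceptor", "splice_donor"}
)

CONSEQUENCE_CLASSES = LOF_CLASSES | {"other"}


@dataclass
class QCThresholds:
    """Quality-control cutoffs. Inequalities are strict except vqslod_min (>=)."""

    vqslod_min: float = -1.5
    dp_min: int = 8           # genotype kept iff DP > dp_min
    gq_min: int = 20          # genotype kept iff GQ > gq_min
    allele_balance_min: float = 0.2   # ALT reads / total reads, strict >
    missingness_max: float = 0.10     # site kept iff missing fraction < this
    maf_max: float = 0.001            # site kept iff control MAF < this

    def __post_init__(self):
        for name in ("allele_balance_min", "missingness_max", "maf_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


def normalize_consequence(raw: str) -> str:
    """Map a consequence string onto the fixed class set; unknowns -> other."""
    c = str(raw).strip().lower()
    if c in CONSEQUENCE_CLASSES:
        return c
    logger.warning("unknown consequence %r mapped to 'other'", raw)
    return "other"


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


@dataclass
class CohortCalls:
    """Parsed cohort VCF: one row per biallelic site, genotype arrays per site."""

    samples: list[str]
    sites: pd.DataFrame  # chrom pos ref alt variant_key vqslod gene consequence
    gt: list[np.ndarray]      # per site: -1 missing, 0 hom-ref, 1 het, 2 hom-alt
    dp: list[np.ndarray]      # per site: read depth, -1 if absent
    gq: list[np.ndarray]      # genotype quality, -1 if absent
    ad_ref: list[np.ndarray]  # allelic depth ref, -1 if absent
    ad_alt: list[np.ndarray]


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def _fmt_int(variant, key: str, n: int) -> np.ndarray:
    try:
        arr = variant.format(key)
    except KeyError:
        arr = None  # field not in header: fail closed
    if arr is None:
        logger.warning("FORMAT field %s absent at %s:%s; genotypes fail closed",
                       key, variant.CHROM, variant.POS)
        return np.full(n, -1, dtype=np.int64)
    return np.asarray(arr, dtype=np.int64).reshape(n, -1)[:, 0]


def read_cohort_vcf(path: str | Path) -> CohortCalls:
    """Read a VCFv4.2 cohort file (single ALT per record, pre-split).

    Raises a ``ValueError`` naming the record number on multi-allelic rows
    or unparseable records.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    rows, gts, dps, gqs, adr, ada = [], [], [], [], [], []
    for i, v in enumerate(vcf, start=1):
        try:
            if len(v.ALT) != 1:
                raise ValueError(
                    f"multi-allelic record (ALT={v.ALT}); split multiallelics first"
                )
            vq = v.INFO.get("VQSLOD")
            gene = v.INFO.get("GENE")
            csq = v.INFO.get("CSQ")
            gt_types = np.asarray(v.gt_types, dtype=np.int64)
            # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt = np.select(
                [gt_types == 0, gt_types == 1, gt_types == 3], [0, 1, 2], default=-1
            )
            try:
                ad = v.format("AD")
            except KeyError:
                ad = None
            if ad is None:
                ad_r = np.full(n, -1, dtype=np.int64)
                ad_a = np.full(n, -1, dtype=np.int64)
            else:
                ad = np.asarray(ad, dtype=np.int64).reshape(n, -1)
                ad_r = ad[:, 0]
                ad_a = ad[:, 1] if ad.shape[1] > 1 else np.full(n, -1, dtype=np.int64)
            rows.append(
                {
                    "chrom": v.CHROM,
                    "pos": int(v.POS),
                    "ref": v.REF,
                    "alt": v.ALT[0],
                    "variant_key": variant_key(v.CHROM, v.POS, v.REF, v.ALT[0]),
                    "vqslod": float(vq) if vq is not None else math.nan,
                    "gene": str(gene) if gene is not None else "",
                    "consequence": normalize_consequence(csq) if csq is not None else "other",
                }
            )
            gts.append(gt)
            dps.append(_fmt_int(v, "DP", n))
            gqs.append(_fmt_int(v, "GQ", n))
            adr.append(ad_r)
            ada.append(ad_a)
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed VCF record #{i} in {path}: {exc}") from exc
    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "variant_key", "vqslod", "gene", "consequence"]
    )
    return CohortCalls(samples, sites, gts, dps, gqs, adr, ada)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def apply_qc(calls: CohortCalls, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Site/genotype QC pass table.

    A genotype passes iff DP > dp_min AND GQ > gq_min AND, for ALT-carrying
    calls, allele balance (ALT depth / total AD depth) > allele_balance_min.
    A site passes iff VQSLOD >= vqslod_min AND the fraction of no-call
    genotypes among cases < missingness_max. The returned frame keeps every
    site, with ``site_pass``, the post-QC ``carriers`` set and a
    ``fail_reason`` audit column (empty when passing with >= 1 carrier).
    """
    thr = thresholds or QCThresholds()
    n = len(calls.samples)
    sample_arr = np.array(calls.samples)
    out = calls.sites.copy()
    site_pass, carriers_col, reasons = [], [], []
    for idx in range(len(out)):
        gt, dp, gq = calls.gt[idx], calls.dp[idx], calls.gq[idx]
        ad_r, ad_a = calls.ad_ref[idx], calls.ad_alt[idx]
        reason = []
        vq = out.at[idx, "vqslod"]
        if not (not math.isnan(vq) and vq >= thr.vqslod_min):
            reason.append("vqslod")
        missing_frac = float((gt == -1).sum()) / n if n else 0.0
        if not missing_frac < thr.missingness_max:
            reason.append("missingness")
        geno_ok = (dp > thr.dp_min) & (gq > thr.gq_min)
        alt_mask = gt > 0
        total = ad_r + ad_a
        with np.errstate(divide="ignore", invalid="ignore"):
            ab = np.where(total > 0, ad_a / np.maximum(total, 1), -1.0)
        ab_ok = np.where(alt_mask, (ad_a >= 0) & (ad_r >= 0) & (ab > thr.allele_balance_min), True)
        carrier_mask = alt_mask & geno_ok & ab_ok & (gt != -1)
        carriers = frozenset(sample_arr[carrier_mask])
        ok = not reason
        if ok and not carriers and alt_mask.any():
            reason.append("genotype_qc")
        site_pass.append(ok)
        carriers_col.append(carriers)
        reasons.append(",".join(reason))
    out["site_pass"] = site_pass
    out["carriers"] = carriers_col
    out["fail_reason"] = reasons
    logger.info(
        "apply_qc: %d/%d sites pass site QC with >=1 carrier",
        int((out["site_pass"] & (out["carriers"].map(len) > 0)).sum()),
        len(out),
    )
    return out


def qc_passing(sites: pd.DataFrame) -> pd.DataFrame:
    """Sites surviving QC with a non-empty post-QC carrier set."""
    keep = sites["site_pass"] & (sites["carriers"].map(len) > 0)
    return sites[keep].drop(columns=["site_pass", "fail_reason"]).reset_index(drop=True)


def read_control_af(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    df.columns = [c.lower() for c in df.columns]
    if not {"chrom", "pos", "ref", "alt", "af"}.issubset(df.columns):
        raise ValueError(f"control AF table {path} needs columns chrom,pos,ref,alt,af")
    df["variant_key"] = [
        variant_key(r.chrom, r.pos, r.ref, r.alt) for r in df.itertuples(index=False)
    ]
    return df


def filter_population_frequency(
    sites: pd.DataFrame, control_af: pd.DataFrame, maf_max: float = 0.001
) -> pd.DataFrame:
    """Keep ultra-rare sites: absent from the control table or MAF < maf_max.

    MAF is min(AF, 1 - AF) of the ALT allele; for genuinely rare sites
    AF = MAF. Absence from the control table is the strongest rarity
    evidence and passes.
    """
    if "variant_key" not in control_af.columns:
        control_af = control_af.assign(
            variant_key=[
                variant_key(r.chrom, r.pos, r.ref, r.alt)
                for r in control_af.itertuples(index=False)
            ]
        )
    af_map = dict(zip(control_af["variant_key"], control_af["af"].astype(float)))
    maf = sites["variant_key"].map(
        lambda k: min(af_map[k], 1.0 - af_map[k]) if k in af_map else 0.0
    )
    kept = sites[maf < maf_max].reset_index(drop=True)
    logger.info("frequency filter: %d/%d sites ultra-rare (MAF < %g)", len(kept), len(sites), maf_max)
    return kept


def select_lof(sites: pd.DataFrame) -> pd.DataFrame:
    """Keep sites whose consequence is a loss-of-function class."""
    csq = sites["consequence"].map(normalize_consequence)
    kept = sites[csq.isin(LOF_CLASSES)].reset_index(drop=True)
    logger.info("LoF filter: %d/%d sites are LoF", len(kept), len(sites))
    return kept


def read_gene_list(path: str | Path) -> list[str]:
    genes = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return [g for g in genes if g and not g.startswith("#")]


def restrict_to_candidates(sites: pd.DataFrame, gene_list: Iterable[str]) -> pd.DataFrame:
    """Qualifying-variant table: sites in candidate genes, case-insensitive match.

    Output columns: variant_key, gene, consequence, carriers (frozenset).
    Variant keys are unique; carrier sets are non-empty by construction of
    the upstream QC step.
    """
    wanted = {g.strip().lower() for g in gene_list}
    if not wanted:
        raise ValueError("candidate gene list is empty")
    mask = sites["gene"].str.strip().str.lower().isin(wanted)
    qv = sites[mask][["variant_key", "gene", "consequence", "carriers"]].reset_index(drop=True)
    if qv.empty:
        logger.warning("restrict_to_candidates: empty intersection with candidate list")
    if qv["variant_key"].duplicated().any():
        raise ValueError("duplicate variant keys in qualifying-variant table")
    return qv


def run_filter_chain(
    calls: CohortCalls,
    control_af: pd.DataFrame,
    gene_list: Iterable[str],
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """QC -> frequency -> LoF -> candidate restriction, in one call."""
    thr = thresholds or QCThresholds()
    sites = qc_passing(apply_qc(calls, thr))
    sites = filter_population_frequency(sites, control_af, thr.maf_max)
    sites = select_lof(sites)
    return restrict_to_candidates(sites, gene_list)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (what the printed percentages use)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class CohortSummary:
    n_cohort: int
    n_carrier_cases: int
    n_variants: int
    n_genes: int
    n_candidate_genes: int
    pct_cases: int
    pct_genes: int
    sharing_histogram: dict[int, int] = field(default_factory=dict)
    n_private: int = 0


def summarize_cohort(qv: pd.DataFrame, n_cohort: int, n_candidate_genes: int) -> CohortSummary:
    """Cohort-level counts and integer percentages (half away from zero)."""
    if n_cohort <= 0 or n_candidate_genes <= 0:
        raise ValueError("n_cohort and n_candidate_genes must be positive")
    if qv.empty:
        return CohortSummary(n_cohort, 0, 0, 0, n_candidate_genes, 0, 0, {}, 0)
    all_cases = set().union(*qv["carriers"])
    n_genes = qv["gene"].nunique()
    sharing = qv["carriers"].map(len).value_counts().sort_index()
    hist = {int(k): int(v) for k, v in sharing.items()}
    return CohortSummary(
        n_cohort=n_cohort,
        n_carrier_cases=len(all_cases),
        n_variants=len(qv),
        n_genes=n_genes,
        n_candidate_genes=n_candidate_genes,
        pct_cases=int(round_half_away(100.0 * len(all_cases) / n_cohort)),
        pct_genes=int(round_half_away(100.0 * n_genes / n_candidate_genes)),
        sharing_histogram=hist,
        n_private=hist.get(1, 0),
    )


def per_gene_burden(qv: pd.DataFrame, n_cohort: int) -> pd.DataFrame:
    """Per-gene variant and distinct-carrier counts with 1-decimal case %.

    A case carrying two qualifying variants in the same gene is counted once
    for that gene. Sorted by descending n_variants, ties by gene symbol.
    """
    if n_cohort <= 0:
        raise ValueError("n_cohort must be positive")
    rows = []
    for gene, sub in qv.groupby("gene"):
        cases = set().union(*sub["carriers"])
        rows.append(
            {
                "gene": gene,
                "n_variants": len(sub),
                "n_cases": len(cases),
                "pct_cases": round_half_away(100.0 * len(cases) / n_cohort, 1),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "n_variants", "n_cases", "pct_cases"])
    if out.empty:
        return out
    return out.sort_values(
        ["n_variants", "gene"], ascending=[False, True], ignore_index=True
    )


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def write_qualifying_table(qv: pd.DataFrame, path: str | Path, header_comment: str = "") -> None:
    out = qv.copy()
    out["carriers"] = out["carriers"].map(lambda s: ",".join(sorted(s)))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_qualifying_table(path: str | Path) -> pd.DataFrame:
    qv = pd.read_csv(path, sep="\t", comment="#")
    qv["carriers"] = qv["carriers"].map(
        lambda s: frozenset(str(s).split(",")) if pd.notna(s) and str(s) else frozenset()
    )
    return qv
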