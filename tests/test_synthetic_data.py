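"""Planted-truth generator: determinism, planted structure, contaminants."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from nsnet.brain_expression import propagate_calls
from nsnet.synthetic_data import (
    SimConfig,
    gene_intervals,
    simulate_all,
    simulate_annotations,
    simulate_cohort,
    simulate_crossref,
    simulate_ontology_and_calls,
    simulate_ppi,
    write_vcf,
)
from nsnet.variant_filter import (
    QCThresholds,
    apply_qc,
    filter_population_frequency,
    qc_passing,
    read_cohort_vcf,
    restrict_to_candidates,
    run_filter_chain,
    select_lof,
)


def file_hashes(d: Path) -> dict:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir())
        if p.is_file()
    }


class TestDeterminism:
    def test_identical_config_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(seed=13, n_genes=20, n_cases=30)
        t1 = simulate_all(cfg, tmp_path / "a")
        t2 = simulate_all(cfg, tmp_path / "b")
        assert file_hashes(tmp_path / "a") == file_hashes(tmp_path / "b")
        assert t1.qualifying_keys == t2.qualifying_keys

    def test_different_seed_differs(self, tmp_path):
        simulate_all(SimConfig(seed=1, n_genes=15, n_cases=20), tmp_path / "a")
        simulate_all(SimConfig(seed=2, n_genes=15, n_cases=20), tmp_path / "b")
        h1, h2 = file_hashes(tmp_path / "a"), file_hashes(tmp_path / "b")
        assert h1["cohort.vcf"] != h2["cohort.vcf"]


class TestPpi:
    def test_deterministic_limit_two_cliques(self):
        edges, truth = simulate_ppi(SimConfig(n_genes=6, n_communities=2, p_in=1.0, p_out=0.0))
        assert len(edges) == 6  # two disjoint 3-cliques
        for row in edges.itertuples():
            assert truth.community_of_gene[row.gene_a] == truth.community_of_gene[row.gene_b]

    def test_no_edges_when_probabilities_zero(self):
        edges, _ = simulate_ppi(SimConfig(n_genes=10, n_communities=2, p_in=0.0, p_out=0.0))
        assert edges.empty

    def test_edge_counts_within_binomial_bounds(self):
        cfg = SimConfig(seed=1, n_genes=60, n_communities=3, p_in=0.3, p_out=0.02)
        edges, truth = simulate_ppi(cfg)
        comm = truth.community_of_gene
        within = sum(comm[r.gene_a] == comm[r.gene_b] for r in edges.itertuples())
        between = len(edges) - within
        pairs_within = sum(
            1 for i in range(60) for j in range(i + 1, 60)
            if comm[f"G{i+1:04d}"] == comm[f"G{j+1:04d}"]
        )
        pairs_between = 60 * 59 // 2 - pairs_within
        for count, n, p in ((within, pairs_within, 0.3), (between, pairs_between, 0.02)):
            mu, sd = n * p, np.sqrt(n * p * (1 - p))
            assert abs(count - mu) <= 3 * sd

    def test_within_confidence_higher_than_between(self):
        edges, truth = simulate_ppi(SimConfig(seed=2, p_in=0.5, p_out=0.2))
        comm = truth.community_of_gene
        w = edges[[comm[a] == comm[b] for a, b in zip(edges.gene_a, edges.gene_b)]]
        b = edges[[comm[a] != comm[b] for a, b in zip(edges.gene_a, edges.gene_b)]]
        assert w["confidence"].mean() > b["confidence"].mean()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            SimConfig(p_in=1.5)


class TestCohort:
    def test_zero_lof_rate_zero_qualifying(self):
        cfg = SimConfig(seed=3, n_genes=10, n_cases=20, lof_rate_per_gene=0.0)
        _, truth = simulate_ppi(cfg)
        simulate_cohort(cfg, truth)
        assert truth.qualifying_keys == set()

    def test_filter_chain_recovers_exactly_planted_sites(self, tmp_path):
        cfg = SimConfig(seed=4, n_genes=25, n_cases=60)
        _, truth = simulate_ppi(cfg)
        cohort = simulate_cohort(cfg, truth)
        vcf = tmp_path / "c.vcf"
        write_vcf(cohort, vcf)
        qv = run_filter_chain(read_cohort_vcf(vcf), cohort.control_af, truth.genes)
        assert set(qv["variant_key"]) == truth.qualifying_keys

    def test_recovered_carriers_match_truth(self, tmp_path):
        cfg = SimConfig(seed=5, n_genes=15, n_cases=40)
        _, truth = simulate_ppi(cfg)
        cohort = simulate_cohort(cfg, truth)
        vcf = tmp_path / "c.vcf"
        write_vcf(cohort, vcf)
        qv = run_filter_chain(read_cohort_vcf(vcf), cohort.control_af, truth.genes)
        for gene, sub in qv.groupby("gene"):
            assert set().union(*sub["carriers"]) == truth.carrier_cases_by_gene[gene]

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_recovery_across_seeds(self, seed, tmp_path):
        cfg = SimConfig(seed=seed, n_genes=12, n_cases=25)
        _, truth = simulate_ppi(cfg)
        cohort = simulate_cohort(cfg, truth)
        vcf = tmp_path / "c.vcf"
        write_vcf(cohort, vcf)
        qv = run_filter_chain(read_cohort_vcf(vcf), cohort.control_af, truth.genes)
        assert set(qv["variant_key"]) == truth.qualifying_keys

    def test_each_contaminant_fails_exactly_its_planted_filter(self, tmp_path):
        cfg = SimConfig(seed=6, n_genes=20, n_cases=50)
        _, truth = simulate_ppi(cfg)
        cohort = simulate_cohort(cfg, truth)
        vcf = tmp_path / "c.vcf"
        write_vcf(cohort, vcf)
        calls = read_cohort_vcf(vcf)
        audit = apply_qc(calls).set_index("variant_key")
        af = {
            f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}": r.af
            for r in cohort.control_af.itertuples(index=False)
        }
        candidate = {g.lower() for g in truth.genes}

        relaxed = {
            "vqslod": QCThresholds(vqslod_min=-1e9),
            "missingness": QCThresholds(missingness_max=1.0),
            "dp": QCThresholds(dp_min=-1),
            "gq": QCThresholds(gq_min=-1),
            "allele_balance": QCThresholds(allele_balance_min=0.0),
        }
        for key, kind in truth.contaminant_filter_of_key.items():
            row = audit.loc[key]
            if kind in ("vqslod", "missingness"):
                assert row["fail_reason"] == kind
                other = apply_qc(calls, relaxed[kind]).set_index("variant_key").loc[key]
                assert other["site_pass"] and len(other["carriers"]) > 0
            elif kind in ("dp", "gq", "allele_balance"):
                assert row["site_pass"] and len(row["carriers"]) == 0
                other = apply_qc(calls, relaxed[kind]).set_index("variant_key").loc[key]
                assert len(other["carriers"]) > 0
            else:
                # passes QC with carriers, then fails exactly its own filter
                assert row["site_pass"] and len(row["carriers"]) > 0
                maf = min(af.get(key, 0.0), 1 - af.get(key, 0.0))
                gene_ok = str(row["gene"]).lower() in candidate
                lof_ok = row["consequence"] != "other"
                checks = {"frequency": maf < 0.001, "consequence": lof_ok, "offlist": gene_ok}
                for name, ok in checks.items():
                    assert ok == (name != kind), (key, kind, name)


class TestAnnotations:
    def test_full_purity_subset_of_one_community(self):
        cfg = SimConfig(seed=7, pathway_purity=1.0)
        _, truth = simulate_ppi(cfg)
        sets = simulate_annotations(truth, cfg)
        for c, name in truth.enriched_pathway_of_community.items():
            members = sets[name]
            assert {truth.community_of_gene[g] for g in members} == {c}

    def test_every_gene_annotated(self):
        cfg = SimConfig(seed=8)
        _, truth = simulate_ppi(cfg)
        sets = simulate_annotations(truth, cfg)
        assert set().union(*sets.values()) >= set(truth.genes)

    def test_seed_fixed_identical_sets(self):
        cfg = SimConfig(seed=9)
        _, t1 = simulate_ppi(cfg)
        _, t2 = simulate_ppi(cfg)
        assert simulate_annotations(t1, cfg) == simulate_annotations(t2, cfg)


class TestOntology:
    def test_dag_acyclic_single_root_and_propagatable(self):
        cfg = SimConfig(seed=10)
        _, truth = simulate_ppi(cfg)
        dag, calls = simulate_ontology_and_calls(truth, cfg)
        assert dag.root == "BR:0000"
        closed = propagate_calls(dag, calls)  # raises on unknown terms
        assert len(closed) >= len(calls)

    def test_few_regions_all_siblings(self):
        cfg = SimConfig(seed=11, n_regions=3)
        _, truth = simulate_ppi(cfg)
        dag, _ = simulate_ontology_and_calls(truth, cfg)
        for t in dag.terms:
            if t != dag.root:
                assert dag.parents(t) == [dag.root]

    def test_signal_boosts_planted_region_calls(self):
        cfg = SimConfig(seed=12, region_signal_strength=8.0)
        _, truth = simulate_ppi(cfg)
        _, calls = simulate_ontology_and_calls(truth, cfg)
        planted_hits = planted_slots = 0
        for g, c in truth.community_of_gene.items():
            planted = truth.enriched_region_of_community[c]
            planted_slots += 1
            planted_hits += (g, planted) in calls
        rate_planted = planted_hits / planted_slots
        assert rate_planted > 0.55  # baseline is 0.3


class TestCrossrefSim:
    def test_planted_evidence_recovered_by_rules(self):
        from nsnet.crossref import filter_cnvs, filter_denovo, select_categories

        cfg = SimConfig(seed=14)
        _, truth = simulate_ppi(cfg)
        denovo, cnvs, cats = simulate_crossref(truth, cfg)
        assert filter_denovo(denovo) == truth.denovo_genes
        _, hit = filter_cnvs(cnvs, gene_intervals(truth.genes))
        assert hit == truth.cnv_genes
        assert select_categories(cats) == truth.category_genes
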