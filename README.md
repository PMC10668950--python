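# nsnet

Rare-variant burden meets network biology: `nsnet` is a pipeline for studies
that ask *which biological processes are disrupted* when ultra-rare
loss-of-function (LoF) variants hit a candidate gene panel — for example
neurotransmission/synaptic genes in an autism cohort. Rather than ranking
single genes, it maps the genes carrying qualifying variants onto a weighted
protein–protein interaction (PPI) network, decomposes that network into
biological communities, and characterizes each community by pathway
overrepresentation, brain-region expression enrichment and independent
cross-dataset evidence.

It is written for statistical geneticists and systems biologists who have:

- cohort variant calls (VCF with per-genotype `DP`/`GQ`/`AD`, per-site
  `VQSLOD`, and gene/consequence annotation),
- a large-control allele-frequency table (gnomAD-style),
- a candidate gene list,
- a confidence-scored PPI edge table (STRING-style),
- pathway gene sets (GMT), an anatomy `part_of` ontology with gene×region
  expression calls, and de novo SNV / CNV / curated-category tables.

A first-class synthetic-data module generates all of these with planted
ground truth (planted community structure, planted rare-LoF burden, planted
pathway and regional-expression signal), so the entire pipeline is testable
end-to-end with no external downloads.

## The method

**Variant filtering.** A genotype supports a variant iff `DP > 8`,
`GQ > 20`, and allele balance (ALT reads / total reads) `> 0.2`; a site
passes iff `VQSLOD ≥ −1.5` and genotype missingness `< 10%`. Sites are kept
when absent from the control panel or at minor allele frequency
`MAF < 0.1%` (ultra-rare), when their consequence is LoF (frameshift, stop
gain, start lost, splice acceptor/donor), and when their gene is on the
candidate list. The result is a qualifying-variant table
(variant × gene × carrier cases) with cohort summaries.

**Community detection.** The genes carrying qualifying variants define the
nodes of a weighted undirected network (edges kept at confidence ≥ 0.4 by
default). Communities are found with an in-package implementation of the
Leiden algorithm — iterated local moving, stochastic within-community
refinement, and graph aggregation — maximising weighted modularity

```
Q = Σ_c [ w_c / m  −  γ (s_c / 2m)² ]
```

(`m` total edge weight, `w_c` intra-community weight, `s_c` community
degree, resolution γ = 1 by default; the constant Potts model is available
for sensitivity runs). Refinement guarantees connected communities; a
seeded generator makes results reproducible; small-graph optima are
verified against exhaustive partition search in the test suite and
`leidenalg` serves as an independent oracle.

**Community characterization.** Each community is tested for pathway
overrepresentation with the one-sided hypergeometric test plus fold
enrichment `(k/n)/(K/N)` and per-community Benjamini–Hochberg correction;
for brain-region expression a parent–child decorrelated hypergeometric test
is run over a `part_of` anatomy DAG after true-path propagation of
expression calls, with per-community Q-values and an average-linkage
heatmap ordering. Network genes are finally cross-referenced against de
novo SNVs (MAF < 0.001 and SIFT/PolyPhen-damaging), multi-algorithm de novo
CNVs (interval overlap), and high-evidence curated categories (1, 2, S).

## Worked example

Simulate a 60-gene, 3-community study of 400 cases and run everything:

```
nsnet run-all --outdir demo --seed 1
```

which prints (abridged):

```
## Qualifying ultra-rare LoF variants
- 96 variants in 52 genes (87% of the 60-gene candidate list)
- carried by 88 cases (22% of 400 cases)
- 91 private variants; sharing histogram {1: 91, 2: 5}

## PPI network
- 52 nodes, 125 edges, average local clustering 0.189

## Communities
- 3 communities; quality 0.5905 after 4 passes

## Top pathway per community
- community 0: PW_PLANTED_C0 (k=13/18, fold=2.89, p_adj=1.55e-06)
- community 1: PW_PLANTED_C1 (k=12/18, fold=2.67, p_adj=4.15e-05)
- community 2: PW_PLANTED_C2 (k=10/16, fold=2.50, p_adj=1.93e-03)
```

Reading: 96 planted ultra-rare LoF sites survive the full filter chain
(exactly the planted set — every contaminant site fails the one filter it
was planted to fail); the 52 genes they hit form a network whose Leiden
partition recovers the three planted communities; and in each community the
planted pathway is the top-ranked enrichment. `demo/` also contains the
qualifying-variant, per-gene burden, community statistics, pathway and
region enrichment tables, the cross-reference evidence tallies, a rendered
region×community heatmap, and a `report.md` tying it together. Every stage
is also available as its own subcommand (`nsnet simulate | filter |
network | communities | enrich | express | crossref`) over plain TSV/VCF/GMT
files, and as library functions.

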