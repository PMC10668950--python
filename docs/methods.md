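# Methods

This note records the models and procedures implemented in `nsnet`, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions that affect results.

## Variant filtering model

The filter chain treats a cohort VCF as a matrix of biallelic sites ×
genotypes (multiallelic records must be pre-split; the reader rejects
multi-ALT rows with the record number). Two levels of filtering apply:

- **Genotype level** — a call supports the ALT allele iff read depth
  `DP > 8`, genotype quality `GQ > 20` and, for ALT-carrying calls, allele
  balance `> 0.2`. Allele balance is ALT-supporting reads over total reads
  at the genotype, taken from `AD`; a depth threshold on raw allelic depth
  would be vacuous at these values, so the balance reading is used. A
  genotype missing any required field fails closed (logged).
- **Site level** — `VQSLOD ≥ −1.5` (the boundary passes) and no-call
  fraction `< 10%`. Missingness is computed over cases only; whether
  controls should enter the denominator is not determinable from typical
  study descriptions, and cases-only is the conservative reading for a
  cases-only VCF.

Population frequency uses `MAF = min(AF, 1 − AF)` of the ALT allele in the
control table; a site absent from the table passes (absence from a
60k-control panel is the strongest available rarity evidence). `MAF = 0.1%`
exactly is removed. LoF is the fixed five-class set {frameshift, stop_gain,
start_lost, splice_acceptor, splice_donor}; unknown consequence strings map
to `other` (logged) and are dropped. Candidate-gene matching is
case-insensitive after whitespace stripping.

The site-level filters (frequency, LoF, candidate restriction) are pure row
filters and commute; the test suite asserts this over all orderings.

Printed percentages round half away from zero: integers for cohort-level
figures, one decimal for per-gene figures. Per-gene burden counts a case
once per gene regardless of how many qualifying variants it carries there.

## Network and communities

Nodes are the genes with qualifying variants; edges come from a
confidence-scored interaction table, kept when both endpoints qualify and
confidence ≥ `confidence_min` (default 0.4, the conventional STRING
"medium confidence" cutoff — the threshold is configurable and logged
because source studies rarely state it). Degree-0 genes are retained: they
carry cases, and per-community case accounting must span every qualifying
gene. Edge confidences are used directly as weights.

Community detection is an in-package Leiden implementation:

1. **Local moving** — queue-based; nodes are visited in a seeded shuffled
   order, each node moves to the neighbouring (or empty) community with the
   largest quality gain, strictly positive gains only, ties broken toward
   the smallest community label; neighbours of a moved node re-enter the
   queue. Strict positivity keeps degree-0 nodes in singletons.
2. **Refinement** — within each community, starting from singletons,
   well-connected nodes merge into well-connected sub-communities with
   probability proportional to `exp(gain / θ)` among non-degrading merges
   (θ = 0.01, near-greedy but able to leave locally suboptimal merges
   unmade).
3. **Aggregation** — the refined partition collapses to a smaller graph
   (intra-community weight becomes self-loop weight; total weight is
   conserved), initialised with the unrefined communities, and the cycle
   repeats until every community is a single aggregated node or
   `max_passes` (50) is reached.

Quality functions: weighted modularity (default, γ = 1) and the constant
Potts model. Quality is non-decreasing across passes (asserted in tests).
Aggregating on the *refined* partition is what guarantees that every
returned community induces a connected subgraph.

Single-node moving only guarantees a local optimum, and on small graphs a
single run stalls on a few percent of instances. `leiden()` therefore runs
`n_restarts = 5` independent restarts with visit orders derived from the
seed and keeps the best partition; this brings agreement with exhaustive
partition search on ≤ 8-node graphs to 96–99 of 100 across independent
graph sets, while remaining fully deterministic given the seed. The
community count is always an output, never a parameter.

Per-community statistics count a case toward every community containing a
gene in which it carries a qualifying variant (cases may appear in several
communities); the percentage denominator is the number of distinct cases
across the whole network.

## Enrichment statistics

Pathway overrepresentation is the one-sided hypergeometric tail
`P(X ≥ k)` for an overlap of `k` community genes with a `K`-gene set in an
`N`-gene universe, `n` the community size — with fold enrichment
`(k/n)/(K/N)` and Benjamini–Hochberg adjustment within each community's
family of tested sets (matching per-community presentation; families are
never pooled across communities). The default universe is the union of all
genes in the annotation collection, the common ORA convention; a
"network genes only" universe is selectable. Both choices are logged
because upstream tools rarely pin them.

Brain-region enrichment runs over a rooted `part_of` anatomy DAG.
Expression calls are first closed upward (true-path rule: present at a term
⇒ present at all ancestors; idempotent). Each non-root term is tested with
the **parent–child union** variant of decorrelated enrichment: the sampling
universe is the set of genes annotated to the union of the term's parents,
which removes the significance a term would inherit from an enriched
parent. The intersection variant is available by flag; on a flat DAG both
reduce exactly to the plain hypergeometric test against the root universe
(asserted against a shared oracle). A term whose parents carry no
annotations yields p = 1, flagged. Per community, p-values are
BH-converted to Q across all tested terms; rows with any Q < 0.05 (the
configurable display threshold) form the heatmap, whose columns are ordered
by average-linkage hierarchical clustering of Euclidean distances between
−log10(Q) profiles.

## Cross-dataset evidence rules

- de novo SNVs qualify at population `MAF < 0.001` (the boundary fails)
  with SIFT "deleterious" OR PolyPhen "probably/possibly damaging" —
  "possibly" counts because upstream sources say damaging without grade;
  records missing both labels never qualify.
- de novo CNVs qualify when flagged de novo and detected by ≥ 2 algorithms;
  a gene is hit on ≥ 1 bp overlap of closed 1-based intervals (a touching
  endpoint counts). No reciprocal-overlap rule is applied.
- category entries qualify with score 1 or 2 or a syndromic flag ("2S"
  satisfies both).

Evidence tallies report per-source counts and the union (a gene with
several sources counted once), per gene and per community.

## Synthetic data: what it emulates, and what it does not

`SimConfig` defaults define the study conditions used throughout the tests
and the acceptance script:

| parameter | default | rationale |
|---|---|---|
| `n_genes`, `n_communities` | 60, 3 | planted-partition size at which recovery is non-trivial but a desk-scale run stays in seconds |
| `p_in`, `p_out` | 0.3, 0.02 | clearly recoverable block structure (within-degree ≈ 6, between ≈ 0.8) |
| `n_cases` | 400 | enough carriers for stable per-community case percentages |
| `n_controls_freq_table` | 60 146 | gnomAD-scale control denominator (provenance only) |
| `lof_rate_per_gene` | 0.9 | most candidate genes carry ≥ 1 qualifying site, so the network spans most of the panel |
| `background_variant_rate` | 0.5 | QC-clean non-LoF sites that the consequence filter must remove |
| `frac_common_contaminant` | 0.3 | fraction of qualifying-site count planted as common (MAF ≥ 0.1%) contaminants |
| `n_pathways`, `pathway_purity` | 12, 0.9 | one planted set per community among uniform decoys |
| `n_regions` | 8 | flat anatomy under a single "brain" root |
| `region_signal_strength` | 8 | odds multiplier for the planted region–community association |

Qualifying sites are planted to pass every filter (carriers recorded per
gene; mostly private, occasionally shared by 2–3 cases, stop gains
dominating the LoF class mix); contaminant sites each fail exactly one
named filter, including the boundary cases DP = 8, GQ = 20, allele balance
0.2 and control AF exactly 0.1%. Control AFs for qualifying sites are
either absent or drawn below 0.08%.

The anatomy DAG is flat by design: under true-path propagation an
intermediate grouping term inherits the signal of a uniquely-planted region
beneath it and — tested against the root universe while the leaf is tested
against the decorrelated parent universe — can out-score the planted region
itself. A flat DAG keeps "which region is enriched" well-posed at the
planted granularity; hierarchical-DAG behaviour (propagation, parent-child
conditioning on intermediate terms) is exercised by hand-built fixtures in
the unit tests. Expression calls model regional *specificity*: community
genes have baseline odds (base presence rate 0.3) multiplied by
`region_signal_strength` in the planted region and divided by it elsewhere;
strength 1 degenerates to no association, which the null tests exploit.

Determinism: one global integer seed; each generator stage draws from
`default_rng([seed, stage_index])`, so outputs are byte-identical for a
fixed config regardless of stage call order.

Not emulated: linkage disequilibrium, realistic mutation-rate or
consequence spectra, trio inheritance, sex chromosomes, multiallelic sites,
overlapping genes, realistic ontology depth or Bgee-style call quality.
Passing tests therefore demonstrate correctness of the pipeline's logic and
recoverability of planted signal under idealised noise — not calibration on
real cohort data.

## Numerical conventions and degenerate inputs

- Hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, N, K, n)`;
  verified against exact rational summation to 1e−12 for N ≤ 60.
- BH via `statsmodels.multipletests(method="fdr_bh")`; verified against a
  literal step-up oracle; adjusted values are ≥ raw p and order-preserving.
- Rounding of printed percentages: half away from zero.
- Edgeless network: modularity defined as 0; Leiden returns all singletons.
- Fold enrichment with an empty set (K = 0) is reported missing (NaN).
- Empty qualifying table: the pipeline skips network-dependent stages and
  the report states that zero variants survived.
- Hierarchy clustering with one column returns the trivial order.

## Problem sizes in tests and the acceptance script

The default test suite and `scripts/acceptance.py` use the `SimConfig`
defaults above: one full pipeline run, community recovery (NMI ≥ 0.9) over
20 independent 60-node simulations, exhaustive-search comparison on 100
random graphs of 4–8 nodes, and 300 random hypergeometric instances with
N ≤ 60. These sizes keep a complete run in seconds while leaving every
claim statistically meaningful.

## Known limitations

- Weighted modularity inherits the resolution limit; CPM is provided but
  not the default, and no multi-resolution scan is performed.
- The parent–child implementation follows the union/intersection variants
  only; topGO's `elim`/`weight` algorithms are out of scope.
- Evidence cross-referencing matches gene symbols (case-insensitively);
  no alias resolution is attempted.
- The VCF reader expects the annotation in `GENE`/`CSQ` INFO keys with one
  gene per site; sites spanning several genes must be pre-expanded.
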