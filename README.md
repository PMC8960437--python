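# crossbind

Cross-species conservation analysis of transcription-factor binding.

Regulatory evolution can be read directly out of ChIP-seq data: when the
same transcription factor is profiled in two species, each binding site
is either **conserved** (bound at the equivalent genomic location in
both species), **species-specific** (bound in one species with no
evidence of binding at the lifted-over locus in the other), or
**indeterminate** (sub-threshold evidence in between). `crossbind`
implements this classification for T-bet (TBX21)-style two-species
ChIP-seq comparisons — human and mouse Th1 cells being the motivating
system — and quantifies what the classes associate with:

* **Target genes.** Each site is assigned to the nearest TSS; 1:1
  ortholog pairs become *conserved*, *alternative* (bound in both
  species but only through species-specific sites), *species-specific*,
  or *unbound* target genes.
* **Expression divergence.** Per-ortholog log2 expression ratios from
  RNA-seq counts (median-of-ratios normalisation, log2(x+1), per-study
  batch centring, per-species zero-centring), Welch's *t* on per-study
  means, per-class means/SDs, tail enrichment (χ²), and an OLS
  regression of the expression ratio on the clamped binding-site count
  difference Δn ∈ [−5, +5].
* **DNA motif content.** FIMO-style PWM scanning with exact
  dynamic-programming p-values (hits at *P* < 0.004), per-site-set motif
  proportions with `prop.test`-convention Wilson confidence intervals,
  and hypergeometric known-motif enrichment between site sets with BH
  selection and per-set min–max normalisation.
* **Transposable elements.** A site overlaps a TE only if its central
  40 bp is fully enclosed by a single TE; class × overlap χ² with
  standardized residuals `(O−E)/√E`, a 10,000-permutation label test,
  class × TE-class residual tables, and Kruskal–Wallis tests on
  midpoint-to-TSS distances.

The key classification rules:

* high-confidence sites: regions covered by a MACS2 peak at *q* < 0.01
  in **every** replicate (consensus);
* coordinates extended ±1 kb and mapped to the other genome through
  UCSC chains, the image taken as a **single spanning range** from the
  first to the last aligned base;
* a site is species-specific only when that image overlaps nothing in
  the union of *q* < 0.1 peaks across the other species' replicates.

Because real inputs (genome builds, chains, GEO ChIP-seq/RNA-seq) are
far beyond desk scale, the package ships a first-class synthetic-data
generator: two ~2 Mb-per-chromosome toy genomes related by a
constructed block chain with 10 % unalignable sequence, planted site
and gene classes, planted motif instances and TEs at class-specific
rates, and negative-binomial counts with study batch effects — all with
recorded ground truth, so every stage of the pipeline is testable
offline and recovery is measurable.

## Worked example

```bash
crossbind simulate --seed 1 --out world/
crossbind all --config world/run_config.yaml --out world/report --seed 1
```

The first command prints

```
world written to world (376 planted sites)
```

and emits every input in standard formats (narrowPeak per replicate,
chains in both directions, GTF, ortholog TSV, TE/blacklist BED, FASTA,
counts + sample TSVs) plus the ground truth. The second runs the whole
analysis; `world/report/site_class_summary.tsv` then reads

```
species  n_sites  fraction_lifted  n_conserved  n_species_specific  n_indeterminate  n_not_lifted
A        182      0.895604         90           57                  16               19
B        190      0.873684         90           59                  17               24
```

i.e. ~90 % of consensus sites have liftable coordinates (matching the
10 % unalignable genome), and the classifier splits the rest into the
planted conserved / species-specific / indeterminate classes.
`class_divergence_stats.tsv` from the same run shows the planted
expression effects recovered (means are on the log2 A/B scale):

```
gene_class   n   mean       sd        p_vs_ref
a_specific   15  2.549580   2.353040  0.000224
alternative  25  -0.080740  2.274230  0.485841
b_specific   15  -1.539630  2.008600  0.057230
conserved    59  -0.424527  1.346330
```

Species-A-specific target genes are strongly A-biased in expression
(planted +1.95), B-specific genes B-biased (planted −1.55), while genes
with conserved binding sit near the planted −0.59 baseline.
`te_permutation_A.json` holds the TE association (observed χ², analytic
and permutation p at n = 10,000 with the seed), and
`motif_proportions.tsv` the per-site-set motif proportions with their
95 % confidence intervals.

The same analysis is callable as a library:

```python
from crossbind import (SyntheticConfig, build_world, inputs_from_world,
                       analyse, PipelineParams)

world = build_world(SyntheticConfig(seed=1))
report = analyse(inputs_from_world(world), PipelineParams(seed=1))
report["site_summary"]           # class counts and lifted fraction
world.gene_recovery(report["gene_table"])  # ground-truth recovery
```

Per-stage subcommands (`consensus`, `lift`, `classify`, `expression`,
`motifs`, `te`) rerun individual stages from the same run config; see
`crossbind --help`.

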