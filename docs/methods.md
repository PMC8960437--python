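# Methods

This note documents the models, rules, and numerical conventions behind
`crossbind`, the defaults of its synthetic-data generator, and what the
test suite does and does not establish about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)` (the
BED/narrowPeak convention); GTF is converted on read (1-based inclusive
→ half-open, minus-strand TSS = largest coordinate). narrowPeak column
9 (−log10 q) is converted back to a probability on read; the `-1`
sentinel yields a missing q and the peak is kept but excluded from
thresholded sets. Interval overlap requires ≥1 shared base pair —
abutting half-open intervals do not overlap. Peak *merging*, however,
follows bp-set semantics (abutting peaks join), matching
GenomicRanges-style `reduce`.

## Consensus sites

High-confidence sites per species: peaks at q < `q_high` (default 0.01)
from all replicates are pooled, merged into contiguous clusters, and a
cluster is kept only if every replicate contributed at least one
qualifying peak. The emitted coordinates are the merged cluster span
(`--consensus union`, default); `intersection` instead emits the base
pairs covered by all replicates. The low-confidence set — "any evidence
of binding" — is the merged union of q < `q_low` (default 0.1) peaks
from any replicate. Blacklist regions are removed from both the
consensus sites and the evidence union after merging: artifact signal
neither defines a site nor counts as evidence against
species-specificity. Replicate counts are free per species (the
motivating datasets have 3 human and 2 mouse replicates).

## Lifting and site classification

UCSC chains are parsed with full arithmetic validation; minus-strand
query coordinates are converted to forward strand (`pos' = qSize − pos
− 1`) before images are formed. An interval's image is the **single
spanning range** from the smallest to the largest aligned image
position, as produced by lifting a range with rtracklayer/liftOver.
When several chains overlap the source, the highest-scoring chain with
at least one aligned base is used alone (ties broken by chain id);
`use_all_chains=True` pools chains and can return
`split_across_chromosomes`. No minimum-match filter is applied — one
aligned base suffices — but `mapped_fraction` is reported so callers
can filter.

Each high-confidence site is padded ±1 kb (clamped at chromosome
bounds), lifted, and classified against the other species:

* `not_lifted` — no aligned base;
* `conserved` — image overlaps a high-confidence site;
* `species_specific` — image overlaps nothing in the q < 0.1 evidence
  union (the "no evidence in any replicate" reading: the union over
  replicates is the only interpretation consistent with requiring
  absolutely no evidence of binding);
* `indeterminate` — otherwise.

Classification runs independently in both directions; counts need not
match across species.

## Target-gene classes

Sites are assigned to the gene with the TSS (any transcript) nearest
the site midpoint, on the same chromosome only; ties break to the
lexicographically smaller gene id. Features on gene-free chromosomes
are dropped from gene-level analyses. On 1:1 ortholog pairs:

* `conserved` — a conserved-class site assigned on both sides;
* `alternative` — species-specific sites assigned on both sides and no
  conserved site on either;
* `a_specific` / `b_specific` — high-confidence sites on one side and
  **no evidence of any kind** on the other (no assigned site of any
  class, and no assigned low-confidence interval);
* `unbound` — everything else. Pairs that carry sites but fit no
  definition are flagged `bound_but_unclassified` and excluded from
  class statistics, mirroring the exclusion of indeterminate sites.

Δn = n_sites_A − n_sites_B is clamped to [−5, +5] for the regression;
the raw value is retained in the output.

## Expression divergence

The negative-binomial differential model that would normally stand
here is deliberately replaced by a fully specified, dependency-free
pipeline, because only normalisation and batch adjustment are needed
before simple cross-species contrasts: per species, median-of-ratios
size factors (reference = per-gene geometric mean over samples with
all-positive counts) → log2(x + pseudocount 1) → per-gene study
centring (subtract study mean, add back the gene grand mean; studies
with one sample are skipped with a warning) → subtraction of the
species grand mean over all genes and samples ("zero-centring", read
as global distribution alignment — per-gene centring would erase the
ratios of interest).

Divergence per ortholog: log2 ratio = mean per-study A means − mean
per-study B means; Welch's unequal-variance t on the per-study means
(one value per study, 3 vs 3 at the defaults), two-sided, unadjusted
(a BH option exists but is off by default). With zero variance in both
groups, p is 1 for equal means. Per-class statistics: mean, SD, Welch
test vs the conserved class, and a two-sided variance-ratio F test vs
conserved. Tail enrichment: per tail, a 2×2 Pearson χ² of
{class-of-interest vs rest} × {beyond ±cutoff (default 5 log2 units)
vs not}; degenerate tables give a missing p with a warning. The
site-count regression is OLS of the log2 ratio on clamped Δn over
genes bound in both species; constant Δn is an error.

Note one small estimator property: because zero-centring subtracts a
grand mean that includes the planted class effects, per-class mean
estimates carry a common offset of order (Σ class effects)/(n genes)
(≈ +0.16 at the generator defaults). This is inherent to the
zero-centring scheme and is well inside the 2·SEM recovery tolerance
at the default class sizes.

## Motif analysis

PWMs load from JASPAR text and MEME minimal formats (columns
renormalised; width ≥ 4). Log-odds use a background-weighted
pseudocount (default 1e-3); a zero background frequency opposite
non-zero motif probability is an error. Scores are discretised to
1/100-bit bins and the exact null distribution of the integer score is
computed by dynamic programming under an order-0 background (estimated
from the scanned sequences unless supplied); −inf scores (motif
probability 0 at pseudocount 0) are tracked as a separate mass.
Scanned windows are scored with the same integer scores, so p-value
lookup is exact with respect to the binning. Both strands are scanned
(the reverse-complement matrix gets its own null when the background
is asymmetric); windows containing N are skipped; a hit is a window
with p below the threshold (default 0.004, the per-position FIMO-style
convention, not per-site).

Motif proportion = fraction of sites with ≥1 hit, with the
`prop.test`-convention continuity-corrected Wilson interval (verified
against R to 1e-9). The continuity-corrected interval is deliberately
conservative (~96–97 % coverage at n = 50); the plain Wilson interval
(`correct=False`) has nominal ~95 % coverage and is the variant the
calibration tests exercise. Known-motif enrichment between disjoint
site sets is a one-sided hypergeometric test on site-level
presence/absence against the pooled sets — a deliberate stand-in for
GC-matched binomial enrichment; the −log10 p matrix is BH-filtered per
site set (q < 0.05 in ≥1 set) and min–max normalised per set, with
non-significant cells flagged.

For lifted-locus site sets the unpadded lift of each specific site is
scanned (padding is for classification only; scanning a ±1 kb image
would dilute proportions).

Limitation worth knowing: at the 0.004 per-position threshold, a
200 bp site accrues ≈ 2·190·0.004 ≈ 1.5 expected chance hits, so
per-site "has a motif" proportions on desk-scale synthetic sites are
background-dominated; the planted class-specific rates are verified
directly against the generator's ground truth, and the scanning
machinery against its exact null, rather than through the proportion
table.

## TE statistics

A site overlaps a TE only when its central 40 bp window (midpoint ±20,
clamped at chromosome ends with a warning) is fully enclosed by a
*single* TE interval; when several enclose it, the longest wins (ties:
lexicographic class, then name). Class × overlap tables are tested
with Pearson's χ² without continuity correction — so the observed
statistic is exchangeable with the permutation null — and cell-wise
standardized residuals `(O−E)/√E` (R `chisq.test()$residuals`; the
literal `(O−E)/E` is available behind `residuals="relative"`). The
permutation test shuffles the overlap flags against fixed class labels
(margins fixed, expecteds precomputed) and reports the add-one
empirical p `(1 + #{null ≥ obs})/(n + 1)` (default n = 10,000, seeded)
**and** the mid-p (half weight on ties). The add-one tie-inclusive
estimate is super-uniform under a discrete null by construction (mean
≈ 0.58 in our null simulations); the mid-p is the calibrated quantity
and is what the uniformity tests check. TSS-distance profiles use
signed midpoint-to-nearest-TSS distances (− upstream, + downstream of
transcription), Kruskal–Wallis on |distance| across classes, and a
signed log-decade binning (≤1 kb, 1–10, 10–100, >100 kb per side).

## The synthetic world

The generator emulates the full study design; its defaults are the
study conditions, chosen once:

| parameter | default | basis |
|---|---|---|
| genome | 2 chromosomes × ~2 Mb per species | full pipeline in seconds |
| aligned blocks / gaps | U(40, 68) kb blocks; gap length set so each species is 10 % unalignable | the 90 % liftable-site regime |
| genes | 85/chromosome, ≥15 kb TSS spacing, 90 % 1:1 orthologs, 30 % with a second TSS | nearest-gene assignment is unambiguous for planted sites |
| gene classes | 60 conserved, 25 alternative, 15 + 15 specific, rest unbound | enough genes per class for 2·SEM recovery |
| sites | 200 bp, at ±1.8–5.4 kb slots around host TSSs (slots ≥1.6 kb apart so a padded lift can only reach its own partner) | |
| replicate q-values | −log10 q ~ N(4.0, 0.75) per replicate; indeterminate evidence q ~ U(0.02, 0.08) in one other-species replicate; ±30 bp boundary jitter | a small, calibrated rate of consensus failures (~1–2 % of sites) so noisy recovery is a real test |
| motif planting | conserved 12.1 % (A) / 13.2 % (B); specific 19.1 %/18.2 % at their own loci, 6.7 %/7.7 % at the lifted loci | the published class-specific motif rates |
| TE planting | conserved 3.4 % (A) / 0.6 % (B); specific 10.8 %/6 %; LINE1/LTR-biased at specific sites; ~25 background TEs/Mb never enclosing a site window | the published class-specific TE rates |
| expression effects (log2 A/B) | conserved N(−0.59, 1.59); alternative N(−0.21, 2.46); A-specific N(+1.95, 2.0); B-specific N(−1.55, 2.0); unbound N(0, 1.2) | published means/SDs; specific-class SDs are a generator choice (the source reports only means) |
| counts | NB dispersion 0.05, 3 studies × 2 samples per species, per-(gene, study) batch factor 2^N(0, 0.25) | typical bulk RNA-seq scales |

Chains are built constructively (alternating aligned blocks and
single-species gaps) and inverted exactly, guaranteeing mutually
inverse chains for round-trip tests. Sites destined not to lift are
drawn binomially at the unalignable rate and placed deep inside gaps;
their hosts are restricted to genes whose class an extra site cannot
change. Decoy peaks (q ≥ 0.1) and blacklisted strong peaks are planted
to exercise filtering. Gene-class ground truth is *derived* from the
planted sites by the classification rule itself and cross-checked
against the planted intent at build time (self-validation); a mismatch
aborts generation. Everything is a pure function of (config, seed):
regeneration is byte-identical.

What the generator does **not** emulate: realistic repeat sequence,
GC/mappability structure, peak-width and signal heterogeneity,
correlated replicate noise, or distance-dependent regulatory decay.
Passing recovery tests therefore demonstrates the correctness of the
pipeline's logic under the stated noise model, not its robustness to
every artefact of real ChIP-seq.

## Numerical conventions and edge cases

Welch df by Welch–Satterthwaite; p floored at the smallest positive
float. χ² requires all margins > 0; degenerate tables in the pipeline
are skipped with a warning rather than aborting a run. The PWM DP
warns if the total probability mass drifts from 1 by >1e-9. The
permutation test seeds a dedicated `numpy` Generator (species B uses
seed+1 so the two species' nulls are independent). Report tables are
written with `%.6g` floats; identical seeds give bit-identical
reports. Sites whose padded lift succeeds but whose unpadded lift
fails keep the padded mapping for classification (scanning, as noted,
re-lifts unpadded).

## Problem sizes used by the test suite

Unit and acceptance tests run the default world (~370 planted sites,
~150 ortholog pairs per world), 20-seed lift-fraction sweeps on
coordinate-only worlds, 2,000-replicate CI coverage simulations, 200
permutation-calibration runs at n_perm = 500, and exhaustive PWM
enumeration up to width 8 — sizes at which every check is exact or has
known Monte-Carlo error, while the whole suite stays in the
couple-of-minutes range.
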