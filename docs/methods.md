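# Methods

This note documents the models and procedures implemented in `regnet`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED native); GTF input (1-based
inclusive) is converted at the reader boundary, with the TSS of a
minus-strand gene taken at its annotated end. A peak's *center* is its
summit when one is present, else `start + floor(length/2)`; the summit is
preferred because asymmetric peaks have off-center binding modes, and the
midpoint is the only defensible fallback. Nearest-TSS ties break to the
lexicographically smaller gene id so results are order-independent.
Chromosome names are taken verbatim (no "chr" normalization). Merging is
a sort-and-sweep that also fuses touching intervals (`end == start`),
so merged output is strictly disjoint.

## Replicate consensus

The consensus procedure replaces a statistical IDR fit with three
documented components:

1. **Reciprocal-overlap matching** — candidate pairs must overlap by at
   least `min_reciprocal_overlap` (default 0.5) of *each* member's
   length; pairs are accepted greedily by descending mean score with
   genomic-order tie-breaks, each peak used once. Greedy-by-score mimics
   the behavior of rank-based reproducibility procedures, which trust
   strong peaks first.
2. **Rank-fraction filter** — only pairs whose both members lie in the
   top `max_rank_fraction` (default 1.0, i.e. off) of their replicate's
   score ranking are retained.
3. **Concordance report** — the Spearman correlation of ranks across
   matched pairs; below `rank_correlation_min` (default 0.5) a warning is
   raised. The correlation is a diagnostic, never a filter, because a
   discordant pair should be inspected, not silently truncated.

The consensus peak is the union span of its two members; its
reproducibility score is `min over members of (1 − rank/set size)`.
This rule is *not* IDR: it has no irreproducibility probability and no
model of the score mixture. What it preserves is the contract — a
conservative, reproducibility-filtered peak set with a concordance
diagnostic — which is the part downstream stages depend on.

## cCRE classification

Elements are classified from three assay signals (DNase, H3K4me3,
H3K27ac) summarized as **max-z scores**: the maximum signal within the
element, standardized (population SD) across the element universe. The
"high" threshold defaults to z ≥ 1.64 (the normal 95th percentile), and
"low" to z < 1.64; setting `low_z < high_z` opens an ambiguity band in
which a signal is neither high nor low, which can only shrink the
classified set (classification is monotone in `high_z`). The distance
thresholds are 200 bp (promoter-proximal, center-to-center) and 2 kb
(pELS/dELS split). Classes are resolved with precedence
PLS > pELS > dELS > DNase-H3K4me3 > DNase-only > unclassified, making the
classifier a total function.

Two annotation paths are implemented. The **catalog path** (default)
assigns each peak the class of its largest-overlap catalog element, ties
to the genomically first element — this matches the common situation
where a published catalog exists. The **distance-rule path** classifies
peaks directly from per-peak signals; it is the right choice when peaks
carry their own signal summaries or when positional noise would break
catalog overlaps.

Signal heatmap matrices around peak centers use bins of `bin_bp` within
`±flank_bp` (defaults 50/2500, giving 100 columns); bins clipped by a
chromosome end are NaN ("absent"), not zero, so row means are not
dragged down at contig boundaries. Rows are ordered by descending mean,
the convention of deepTools-style occupancy heatmaps.

## Co-occupancy

Co-occupancy scores are **length-weighted mean signals** over the merged
region set (uncovered bases count as zero); a mean rather than a max is
used because the score feeds a rank correlation, where a max would be
dominated by single-bin spikes. Factor similarity is Spearman
correlation across regions — invariant to monotone transforms of any
factor's signal scale, which matters because fold-enrichment tracks from
different experiments are not on a common scale. Regions with zero
signal in every factor carry no rank information and are dropped (the
count is logged); a factor with zero variance gets correlation 0 with a
warning rather than NaN. Clustering is agglomerative on distance 1 − ρ
with **average linkage** (configurable to complete); average linkage is
the standard choice for correlation heatmaps and the dendrogram is
exported as Newick. A Jaccard matrix over merged-region occupancy is
emitted as a secondary, signal-free similarity, since "level of overlap"
heatmaps in the literature are sometimes occupancy- rather than
signal-based.

## Regulatory domains and association

GREAT's published basal-plus-extension defaults are adopted: basal
domain 5 kb upstream / 1 kb downstream of the canonical TSS (first by
genomic order when a gene has several), extension up to 1 Mb per side
but stopping at the nearest neighboring gene's *basal* domain, clipped
to the chromosome. Consequences worth knowing: extended domains of
neighboring genes overlap each other (each extends to the other's basal
edge), so an intergenic peak can associate with both flanking genes; but
a peak inside one gene's basal domain belongs to that gene alone.
Association is by peak center (GREAT's rule); a whole-peak-overlap mode
exists behind a flag. The curated-domain and two-nearest-genes GREAT
variants are not implemented.

## Network inference

An edge TF → gene requires a peak that (i) lies in a promoter- or
enhancer-like signature (PLS, pELS or dELS) and (ii) associates with the
gene. Edges carry their full evidence list (peak, class) and a weight
equal to the evidence count; the weight is metadata — the network itself
is binding-based and unweighted, and no expression filter is applied to
edges. Self-loops are retained. Degree statistics are reported both over
all targets and restricted to the TF panel (a TF's "interconnectivity"),
via an explicit TF → encoding-gene map (identity by default).

## Expression processing

CPM uses normalized library sizes: `count / (lib_size × factor) × 1e6`.
The low-expression filter retains genes with CPM ≥ 1 in ≥ 3 samples.

**TMM** follows the published recipe: reference = sample whose count
upper quartile is closest to the mean upper quartile; per-gene log-ratios
M and abundances A on doubly-expressed genes; two-sided trimming of 30%
on M and 5% on A; factor = 2^(inverse-asymptotic-variance-weighted mean
of surviving M); factors rescaled to geometric mean 1. `lib_sizes`
defaults to column sums, in which case factors measure composition bias
only. Passing explicit *nominal* library sizes lets the factor absorb
planted depth differences — this is how the package defines a "planted
normalization factor" in simulations: a per-sample multiplier on
expected counts relative to the nominal size `sum(mu)`, which is exactly
what TMM against nominal sizes recovers. With column-sum library sizes a
uniform depth multiplier is invisible to TMM by construction.

**DE calling** consumes a (gene, log2FC, FDR) table and thresholds at
FDR < 0.05 and |log2FC| > 0.2. The fold-change threshold is applied
symmetrically to both directions. For synthetic runs, a substitute
two-group **NB exact-style test** is provided: counts are scaled to a
common effective library size, a common dispersion is moment-estimated
(`E[s²] = m + φm²`, pooled ratio estimator over genes and groups,
clipped at 0), and the group sums are compared conditionally on their
total — each group sum is NB with size n/φ, and the two-sided p-value
sums all splits with probability ≤ that observed (degenerating to the
conditional binomial as φ → 0). This is deliberately not a
quasi-likelihood GLM: no per-gene dispersion shrinkage, no batch terms.
Measured on 400 null genes (4 vs 4, φ = 0.1) its rejection rate at
α = 0.05 averages ≈ 0.05 across seeds. Benjamini–Hochberg is the
multiple-testing procedure throughout.

**Bound × DE overlap** reports |bound ∩ down| / |bound| (and the up
analogue), 2×2 contingency tables against the gene universe, and
one-sided hypergeometric enrichment p-values. Because the interesting
denominators differ between analyses, callers choose the bound-gene
universe; the pipeline reports the promoter-bound set when class
annotations are available, else all bound genes.

**Z-score clustering** of DE genes scales each gene's CPM to mean 0 /
SD 1 across samples and clusters genes and samples with Euclidean
distance and complete linkage; zero-variance genes are dropped with a
warning (their Z-score is undefined).

## Motif scanning and enrichment

IUPAC consensus matching is exact set membership per position; sequence
characters outside ACGT match only the motif code N. Scanning reports
all overlapping hits on both strands (the reverse strand tests the
reverse complement against forward coordinates). The enrichment
statistic is sequence-level — the fraction of sequences with ≥ 1 hit —
matching the convention of motif-enrichment suites; a hit-count
statistic would conflate enrichment with hit clustering inside single
sequences.

The background defaults to **dinucleotide shuffles** of the foreground
(Altschul–Erickson Eulerian-path shuffle, exact dinucleotide counts
preserved, deterministic under a seed). Ten shuffles per foreground
sequence are generated: the one-sided binomial test treats the
background fraction as known, so the background must be large enough
that its sampling error is negligible — at a 10:1 ratio the variance
inflation is ~5% and the measured null rejection at α = 0.05 stays
within [0.025, 0.075]; at 1:1 the same test would reject ~12% of nulls.
A user-supplied background FASTA is supported. A GC- or
repeat-matched genomic background (as de novo suites use) is *not*
implemented; for genomes with composition structure the shuffle
background is the more conservative and more portable choice.

## Synthetic data: what it emulates, and what it does not

The generator produces a desk-scale study: 2 chromosomes × 5 Mb,
300 genes (TSSs ≥ 20 kb apart so neighboring basal domains are disjoint),
a catalog of 300 elements per class whose planted signals (z ≈ 3 for
"high", z ≈ −1 for "low", ± 0.3 noise) sit far outside the ambiguity
band, a 500-peak target TF set with class proportions
0.48/0.134/0.097/0.10/0.09 (PLS/pELS/dELS/DNase-H3K4me3/DNase-only,
remainder unclassified) mirroring a promoter-heavy binding profile, a
13-TF panel in two co-binding groups (within-group signal correlation
0.8, between 0.0, realized through shared group latents), an 8 TF ×
38 target planted edge table realized as peaks within 150 bp of target
TSSs, 4 + 4 NB count samples at dispersion 0.1 with 10% DE genes at
|log2FC| = 2, and random sequence with the consensus planted in 30% of
target peaks. Signal tracks are rectangular blocks — the simplest model
under which length-weighted means and max-z scores are analytically
checkable. All generators are driven by one `numpy` Generator seeded
from the config, so outputs are byte-identical across runs.

What passing these tests shows: the implementations compute what they
claim (oracle equivalence), recover planted structure when the structure
matches the model assumptions, and are statistically calibrated under
the generator's null. What they do not show: robustness to the spatial
autocorrelation, copy-number structure, mappability artifacts, GC bias
and dispersion heterogeneity of real chromatin and expression data —
none of which the generator emulates. Scale choices (problem sizes in
the tests and acceptance script) were made so a full run completes in
well under a minute per stage on one core.

## Numerical and degeneracy choices

- Ranks are assigned by descending score with genomic-order tie-breaks;
  all orderings (peaks, edges, leaf orders, file rows) are deterministic.
- Zero variance anywhere it would poison a statistic is an explicit
  error (max-z standardization, Z-scores with one sample) or a warned
  degradation (flat factor in Spearman, flat gene in clustering).
- Spearman of a matched pair set with fewer than 2 pairs, or with tied
  constant ranks, is reported as 1.0 (no evidence of discordance).
- The exact NB test rounds library-size-adjusted group sums to integers;
  at the simulated depths this perturbs p-values negligibly.
- `merge` is idempotent; `overlap` uses half-open semantics everywhere
  (adjacent intervals do not overlap).
- Pipeline outputs contain no timestamps; wall-clock times go to the log
  only, so identical config + inputs give byte-identical outputs.

## Known limitations

- Only two replicates are supported by the consensus stage (pairwise
  matching); more replicates require running pairwise combinations.
- The consensus rule has no irreproducibility probability; its
  `reproducibility` score is rank-based bookkeeping, not an error rate.
- The NB substitute test assumes a common dispersion and two groups; it
  is a stand-in for a proper GLM analysis, clearly so labeled.
- H3K4me1 is passed through for heatmaps but plays no role in
  classification, matching the class definitions used.
- PWM/log-odds motif scoring and de novo discovery are out of scope;
  only IUPAC consensus scanning is provided.
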