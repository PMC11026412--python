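# Methods

This note records the models, conventions and numerical choices behind the
package, in the order the pipeline applies them.

## Coordinates and tag model

All internal coordinates are 0-based half-open; GFF3's 1-based closed
convention is converted only at parse/serialize boundaries. The atomic unit
is a *collapsed tag*: an aligned interval with strand, a copy count (reads
collapsed into the tag) and a placement count `n_hits`. Every weighted tally
uses `count / n_hits`, so multi-mapping tags contribute unbiased totals.
Strand is mandatory — antisense orientation relative to the annotated gene
is the operational definition of a ct-siRNA, distinguishing RDR-derived
siRNAs from sense degradation fragments.

## Locus classification

A tag belongs to a feature when ≥50% of its length overlaps the feature's
full genomic span. Overlapping features compete by category priority
structural RNA > pri-miRNA > protein-coding > pseudogene&TE > non-coding
RNA; within a category, larger overlap wins, then the lexicographically
smaller gene id. The priority order exists because rRNA/tRNA fragments
dominate sRNA libraries and must never leak into ct-siRNA counts. These two
rules (overlap fraction, priority) are the pipeline-sensitive conventions of
the classifier: published category percentages rarely state them, so both
are explicit here and checked against a brute-force scan in the tests.
Category percentages are reported over assigned tags; unassigned weight is
carried separately. The tabulated size window is 20–24 nt (configurable).

## Normalization and the differential test

Two normalizations serve different purposes. TPM (`count / library_total ×
1e6`, with the library total counting *all* mapped in-range tags) is used
for reporting, ranking and stage dynamics. The count model uses
median-of-ratios size factors (median ratio to the genewise geometric-mean
pseudo-reference over genes with no zeros; library-size factors as fallback
when no such gene exists), because a handful of explosive hotspot genes
would otherwise drag every other gene's fold change.

The differential test is a self-contained negative-binomial Wald test.
Genewise dispersions come from pooled within-group method-of-moments on
size-factor-normalized counts; a mean–dispersion trend α(μ) = a₀ + a₁/μ is
fitted by least squares over informative genes. With the 3-replicate designs
this pipeline targets, genewise moments estimates carry ~2 degrees of
freedom and are essentially noise, so the working dispersion is the trend
value, escalated to the genewise estimate when that estimate exceeds twice
the trend (a guard against genuine dispersion outliers). Group means are
fitted by vectorized Newton iterations on the NB log-likelihood with
size-factor offsets; the Wald statistic on log2FC is referred to the
standard normal. Empirically (seeded simulations in the test suite) this
yields a raw-p type-I rate of ≈0.04 at nominal 0.05 for 3v3 null data and
full power on an 8-fold planted effect at mean 200, dispersion 0.05.

Conventions at the boundary: genes where one side's normalized mean is zero
report `log2(( m₁ + 1)/(m₀ + 1))` so heatmaps stay finite; all-zero genes
report log2FC 0 with padj NA; genes below a baseMean floor (default 1) are
excluded from testing before Benjamini–Hochberg correction (an independent
filter, so it cannot bias the tested p-values). BH is the textbook step-up
procedure, verified property-wise against the direct formula. The caller
uses `padj < 0.05` and `|log2FC| > 1`.

With 1v1 contrasts the within-group moment estimator is undefined; the
dispersion is then borrowed entirely from the trend fitted on the pooled
samples, and results should be read as exploratory.

## Hotspot ranking

Sources are ranked by replicate-mean antisense 22-nt TPM, descending, ties
broken by gene id (stable and permutation-invariant). Shares are fractions
of the total over all source genes; the top-N share is their cumulative sum.
The hotspot union is the set union of per-genotype top-N (default N = 20)
with a genotype × gene membership matrix. Sense-strand reads never enter
hotspot abundance. Sample clustering uses Euclidean distance and complete
linkage on the genes × samples matrix of log2 ratios to the control mean;
scipy's deterministic linkage plus fixed column order make the dendrogram
(and its Newick export) reproducible.

## Gene features and GC

GC content is (G+C)/(A+C+G+T) with ambiguity codes excluded from both
numerator and denominator. GC classes: low iff GC ≤ 0.30, high iff GC ≥
0.50, else medium — boundaries inclusive, verified bit-exactly. Genome GC
context is computed by splitting each CDS into 100-bp bins, keeping (and
flagging) the trailing partial bin. Gene-body GC defaults to the mature
(exonic) sequence, with a flag to use the full genomic span instead — the
choice matters for intron-rich genes and published figures rarely say which
was used, so both are one flag apart. Flank windows (default 1 kb) are
clipped at contig edges rather than dropped, and clipped genes are recorded.
Producer vs non-producer feature comparisons use Welch's two-tailed t-test
with group summaries.

Metagene profiles use a fixed 50 + 100 + 50 bin grid (1-kb flanks at 20
nt/bin; gene body linearly rescaled to 100 bins), oriented 5'→3' on the gene
strand. Body coverage counts antisense-assigned tags only; flanks count both
strands, since flanks carry no mRNA orientation. The grid is an artifact
choice — published curves are smooth without stating bins.

## Stage dynamics

The stage filter keeps genes with TPM strictly greater than 10 in at least
two stages and a maximal pairwise |log2((TPMᵢ+1)/(TPMⱼ+1))| strictly greater
than 1; the +1 pseudocount keeps comparisons at zero defined, and the strict
inequalities make the filter bit-exact. The max-minus-min shortcut on
log-transformed values is equivalent to the all-pairs scan (tested against
it). Trajectories are z-scored per gene (zero-variance rows become all-zero
and are flagged), clustered with Euclidean/complete linkage and cut to k
flat clusters; k is a parameter (the reference analyses used 18 on hundreds
of genes; the desk-scale drivers use 6 on dozens). Cluster trends are
labelled by Spearman correlation of the mean trajectory with stage order:
increasing at ρ ≥ 0.8, decreasing at ρ ≤ −0.8, else other.

## Fragment analysis

CDSs are cut into consecutive 600-nt fragments named GENE-1…GENE-k from the
5' end; a trailing remainder is kept as a flagged partial fragment but
excluded from GC ranking by default (how published fragment sets handled
remainders is unstated, so it is a parameter). Fragments at ≥55% GC carry a
silencing-risk flag (threshold configurable). Fragment homology is computed,
not delegated to a web tool: shared exact 20-mers on both strands plus best
local alignment under match +1 / mismatch −2 / gap −2.5 (Smith–Waterman via
Biopython's PairwiseAligner, verified against an exhaustive DP in the
tests); the "homologous" verdict is shared k-mers > 0 or ≥80% identity over
≥100 aligned columns. Spreading metrics partition antisense coverage in CDS
coordinates into inside / 5'-ward / 3'-ward of a fragment's cognate
interval; the trans fraction is homolog / (source + homolog) antisense
abundance.

## Synthetic data: what it emulates, and what it does not

The generator builds genomes whose genes carry exact-GC sequences: every
segment (UTR, CDS chunk, intron) contains exactly `round(gc·len)` G+C bases,
so realized GC matches its target to rounding at any granularity. Genes are
separated by ≥2 kb so 1-kb flanks never overlap neighbors. Protein-coding
genes have 5'UTR, CDS split by 0–3 introns, and 3'UTR; other categories are
single-span loci.

Libraries are drawn hierarchically per read — category, then gene (weighted
by a monotone GC effect and a per-stage trend), strand (antisense with the
configured probability for coding loci; both strands equally for others),
length 20–24 from the size mixture, and a uniform placement inside the gene
span — then collapsed, so copy counts sum exactly to the library size.
Per-sample seeds derive from the base seed and the sample name, so adding a
sample never perturbs existing ones.

The default study: Col-0 (structural-RNA-dominated, 10% antisense fraction,
no hotspots) versus two mutants (`ed4`, `sd4`) with 40–45% protein-coding
tags, 22-nt-peaked size mixtures, 75–80% antisense fraction, and 85% of
antisense coding tags concentrated on 20 hotspot genes (sharing 12 between
the mutants, so the expected top-20 union is 28). Gene production weights
follow exp(6·(GC − 0.44)). The time-series design gives one library per
stage over five stages with planted increasing / decreasing / peaked / flat
archetypes cycling over genes.

What the simulation does *not* model — and what passing tests therefore do
not show about real data: sequencing error and adapter artifacts,
multi-mapping (every simulated tag has one placement; the classifier's
`count/n_hits` weighting is exercised only by hand-built fixtures),
overlapping gene models, RNA secondary structure, phasing, and the actual
enzymology of RDR6/DCL2/DCL4. Recovery results demonstrate correctness of
the bookkeeping and statistics under the assumed mixture structure, not
biological fidelity.

## Problem sizes

The drivers and the acceptance script run a desk-scale study: 92 genes (60
protein-coding) on two ~215-kb chromosomes, 100k tags per library, three
replicates per genotype, five stages at one replicate, and 20–100
simulation replicates for calibration/power studies. These sizes keep every
stage's multinomial and NB noise small relative to the planted effects
while the full pipeline remains fast enough to re-run end to end routinely.

## Known limitations

- The NB test is calibrated for the small-replicate regime by design;
  with many replicates the full-trend anchoring is conservative relative to
  genewise empirical-Bayes shrinkage.
- `ct_sirna_counts` tabulates one placement per tag; for genuinely
  multi-mapping real data the per-placement weighting is correct but
  coverage tracks count each placement independently.
- The metagene body rescaling averages per-base coverage into bins; genes
  shorter than 100 bp would alias (the generator never emits them).
- Fragment similarity reports one best local alignment; paralog families
  with multiple repeat blocks are summarized by their strongest block plus
  the k-mer count.
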