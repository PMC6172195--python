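# Methods

## Model and procedure

`regswitch` operationalizes regulatory repurposing as a set of interval
predicates over per-species annotations joined by orthology projection.
All coordinates are 0-based half-open; BED/narrowPeak are native, GTF is
converted at the boundary (`start-1, end`); the TSS is the first
transcribed base (smallest exon start on `+`, largest exon end on `-`).

A locus is a **P/E element** when (i) it is called an enhancer in species
A, (ii) its reciprocal ortholog in sister species B overlaps, by at least
one base, the 500-nt window upstream of the TSS of a transcript that is
*stable* in B (mean replicate FPKM strictly > 1 in an organ and genomic
span strictly > 1000 nt), and (iii) it is not explained by a 5′-truncated
isoform of a locus that also has a stable isoform with a strictly
upstream TSS (strand-aware). When the projection overlaps windows of
several transcripts, the transcript whose TSS is nearest the projection
midpoint is attached (ties to the smaller TSS coordinate). Elements are
*novel* when the B transcript's exonic span, projected back to A,
overlaps no A transcript (or cannot be projected), *extended* otherwise.

**Element calling.** Enhancers are DHSs overlapping an H3K27ac and/or
H3K4me1 consensus peak, with two exclusions: a gap of less than 1000 nt
to any H3K4me3 peak from any tissue (overlap counts as distance 0), and
any overlap with the exons or the 1000-nt TSS-upstream window of any
transcript, stable or unstable. Consensus peaks keep the top 20,000
(H3K4me3) or 80,000 (H3K27ac, H3K4me1) peaks per replicate by score,
cluster them by ≥1-bp overlap across replicates, require support from ≥3
replicates (both when only two exist; every peak when a single merged
sample is given), and emit 1000 nt centered on the summit of the
highest-score supporting peak, clipped at contig ends (the length
invariant is therefore min(1000, contig)). Promoters are the 1000 nt
upstream of each stable TSS, with identical intervals from TSS-sharing
isoforms merged. Inactive controls are rejection-sampled (≤50× target
proposals) non-overlapping 1000-nt loci at least 1000 nt from every DHS,
mark peak, exon, and mask interval.

**Projection.** Orthology is represented as gapless co-linear blocks
(equal source/target lengths; indels between blocks) rather than UCSC
chains — the projection contract, not the file dialect, is what the
analysis needs. An interval projects when the fraction of its bases
covered by blocks reaches the minimum match (0.6 between sisters, 0.4
toward the outgroup); the target is the span from first to last mapped
base, failing on multi-chromosome hits and on spans stretched beyond 10×
the source length (an arbitrary but generous cap against rearrangement
artifacts). Strand flips with the orientation of the majority of covering
blocks. The reciprocal filter accepts a projection only when its
back-projection overlaps the source by ≥1 bp — overlap, not identity,
because block fragmentation legitimately erodes edges.

**Polarization.** The outgroup state of a projected element is
*promoter* when it overlaps the 1000-nt upstream window of a stable
outgroup transcript, else *enhancer* when it overlaps an H3K27ac peak
that itself overlaps no H3K4me3 peak, transcript window, or exon, else
*none*; promoter precedence follows from the enhancer definition's own
exclusions. Ancestral elements are reference elements aligned to both
other clade species (reciprocal for the sister leg, single-direction for
the outgroup leg) whose outgroup ortholog retains the matching activity
(promoters associate through a 500-nt window; this association window is
deliberately distinct from the 1000-nt promoter window and both are
config fields). The turnover table counts repurposed (P/E membership for
enhancers; sister-enhancer signature without promoter conservation for
promoters) versus lost (no conservation) per row; conserved elements
appear only in the totals. The odds ratio is the plain cross-product
ratio and the p-value a two-sided Fisher's exact test (sum of
hypergeometric point probabilities not exceeding the observed one) —
this convention is what reproduces the published borderline p = 0.056
to three decimals.

**Composition.** GC content excludes N from the denominator; CpG
frequency is CG count over dinucleotide positions (length − 1), the
self-consistent choice given the counting unit (a strict mode also drops
N-containing positions from the denominator). The orthologous-shift test
compares the mean B−A difference at P/E pairs with a null of 10,000
resamples of equally many orthologous inactive pairs, drawn without
replacement; because inactive pairs ride the same projection pipeline,
the null carries genome-wide compositional drift. The empirical p uses
the add-one convention (1 + #extreme)/(n + 1), one-sided "greater" by
default, so it is never zero; a Wilcoxon signed-rank p on the tested
pairs is reported alongside.

**Motif axis.** U1 and PAS are scored as log-odds PWMs against a uniform
background on both strands; a hit is any window at or above the matrix
threshold, reported at its forward-coordinate start. The shipped default
matrices are built from the canonical donor core (GT at +1/+2) and the
canonical PAS hexamer with its main variant; thresholds admit exactly
{GTAAGT, GTGAGT} and {AATAAA, ATTAAA} (<0.05% of random hexamers).
Absolute genome-wide densities are therefore threshold-dependent; only
contrasts and asymmetries are interpreted. Densities are counted by hit
start in sense-oriented windows (200–1000 nt) around the TSS, ignoring
hit strand — the sense/antisense contrast comes from which side of the
TSS is measured; windows truncated by contig ends use the effective
length. Between species, the promoter-side TSS is projected to the
enhancer species through the block map (nearest mapped base within 50 nt,
else the pair is dropped), and only novel elements enter cross-species
comparisons, since shared downstream exons of extended loci would
conflate the signal. Paired profiles are compared per (side, window)
with Wilcoxon signed-rank tests, BH-corrected across the whole
side × window family; a hit exactly at the TSS counts downstream at
distance 0; in the U1-before-PAS statistic, a TSS with downstream U1 but
no PAS counts as a success and a TSS with neither motif leaves the
denominator.

**Statistics.** All tests route through one kernel: scipy's Fisher exact
(two-sided point-probability convention), Mann–Whitney U (exact when
n+m ≤ 12 without ties, else normal approximation with tie and continuity
corrections), Wilcoxon signed-rank (zeros dropped, exact for n ≤ 12),
and statsmodels' BH step-up. Signal comparisons use
log2((chip + 1)/(input + 1)) per element — the unit pseudocount guards
zero-input regions. Every test in the suite is cross-checked against an
independent enumeration oracle at small n.

## Synthetic data: what it emulates, and what it does not

The generator builds a three-species clade (reference A with enhancer
chromatin, sister B with promoter-side activity, outgroup O) from one
ancestral i.i.d. sequence (default GC 0.41) per chromosome, diverged by
i.i.d. substitutions (default 0.005/base), with identity block maps
optionally fragmented by `block_break_rate` (default 0: the noise-free
regime). Elements occupy a 10-kb slot grid so the 1000-nt exclusion
rules hold by construction. Per planted P/E event: A gets DHS + H3K27ac
replicate peaks over the 1000-nt site; B gets a stable transcript whose
TSS sits at the site edge so the 500-nt upstream window falls inside the
projected site; extended events add a shared downstream locus transcribed
in both species, with the planted transcript as its new 5′ isoform.
Outgroup states (default 40% enhancer, 4% promoter, rest none), conserved
and lost enhancers/promoters, and one promoter-to-enhancer event populate
the turnover table. Decoys exercise the filters: bivalent loci (H3K4me3
500 nt away), truncated-isoform pairs, and unstable transcripts.

Planted contrasts are the biological quantities under test: the B-side
element is topped up with CG dinucleotides until its CpG frequency
exceeds the A side's by `pe_cpg_shift` (default +0.02, chosen for
testability — the source material reports the shift only
distributionally); U1 consensus strings are planted at
Poisson-distributed grid positions at 3.0/kb downstream of the promoter
TSS versus 2.0/kb at the orthologous enhancer side, with equal upstream
rates (2.0/kb) so the upstream comparison is a true null; PAS rates are
mildly reversed (1.45 vs 1.70/kb). Exact-consensus planting separates
generator correctness from scanner thresholds. FPKM replicates are
lognormal (μ = 2.0, σ = 0.5) around a stable mean, with an unstable
class pinned below the threshold.

What the generator does **not** emulate — hence what passing tests do
not show about real data: realistic substitution processes or indel
spectra (no phylogenetic model), peak-calling noise and replicate
disagreement (replicates differ only in score jitter), repeat-driven
element turnover, background transcription, one-to-many orthology, or
chromatin heterogeneity across organs (a second organ exists only to
exercise organ filters). Recovery of planted parameters demonstrates the
correctness of the pipeline's logic, not its robustness to real-world
annotation error.

## Problem sizes and numerical choices

Default study conditions: 4 chromosomes × 600 kb, 50 planted P/E events
(half novel), 120 enhancers, 100 promoters, 500 inactive regions, three
replicates; the motif-axis comparison uses a 5-chromosome variant with
100 all-novel events, the scale at which the downstream U1 contrast is
reliably significant while the upstream null stays flat. The resampling
null uses 10,000 draws (tests use 200–400 where only calibration is
asserted). A full default run completes in ~2 s on one core; the
acceptance script (both clades plus all printed-table statistics) in
~5 s.

Tie-breaks and degenerate inputs: peak-score ties at the top-n boundary
break by (contig, start); GC matching processes enhancers in (gc, id)
order and resolves equidistant inactive candidates toward the lower GC
(with a 1e-12 float guard); empty organs, all-zero contingency tables,
zero-length pools, and sub-matrix-length sequences raise explicit errors;
all-zero difference vectors return p = 1 with a warning. All randomness
flows from a single integer seed through numpy Generators (stage seeds
spawned via SeedSequence); identical seeds give byte-identical outputs,
enforced by manifest digests.

## Known limitations

- Orthology maps are gapless co-linear blocks; UCSC chain/net import is
  out of scope, as are chain scoring and multi-mapping.
- Default U1/PAS matrices are consensus-derived stand-ins, not
  data-derived motifs; users with organism-specific matrices should
  supply them via the 4-row text format.
- The inactive-control and GC-matching machinery assumes element-scale
  (≈1 kb) intervals; very short contigs relax the length invariant to
  the contig size.
- Per-organ enrichment denominators, CGI stratification, conservation
  scoring, and core-promoter motif enrichment are outside the package's
  scope.
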