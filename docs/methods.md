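# Methods

This note documents the models, parameter choices and numerical conventions
behind `methylscape`, and what the synthetic-data tests do and do not show
about real data.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED) after ingestion; cytosine
reports (1-based) are shifted on read. Chromosome names are compared by
exact string match — no `chr` aliasing — and a preflight check
(`core.check_chrom_names`) reports disjoint name sets between inputs instead
of silently returning zero overlaps. The interval engine
(`intervalops`) is a sweep-line implementation of merge, intersection,
subtraction, genome complement and overlap-pair enumeration; every operation
is verified in the test suite against quadratic and per-bp bitmap oracles
and cross-checked once against pyranges.

## Methylation scores and smoothing

The raw score at a CpG is m/(m+u), undefined (NaN, never zero) at uncovered
sites; minus-strand calls are collapsed onto the + strand C of the CpG
dinucleotide, summing counts. Smoothing follows the BSmooth idea: for each
CpG the smallest centered window spanning at least `min_window_bp` (default
1000) and containing at least `min_cpgs` (default 70) CpGs, widened
symmetrically by distance when the base window is too sparse; weights are
tricube in distance multiplied by per-site coverage, so deeply covered
neighbours dominate. Chromosomes with fewer than `min_cpgs` sites fall back
to the coverage-weighted chromosome mean and are flagged. Smoothing is a
weighted mean, hence bounded by the local raw range and shift-equivariant;
both are property-tested. The defaults are the established convention for
this smoother; both are exposed.

A practical consequence of a 70-CpG window: features much narrower than the
window (e.g. 15-CpG low-methylated islands in a high background) are
attenuated above the 0.5 segmentation cutoff and will not segment
end-to-end. This is a property of any smoothing-based segmentation at these
parameters, and is why the classifier is specified — and tested — on region
statistics independently of the segmenter.

## UMR/LMR segmentation and classification

Candidate regions are maximal runs of consecutive CpGs with smoothed score
below 0.5; runs separated by ≤ 500 bp are merged and runs with < 4 CpGs
dropped; bounds run from the first to last contributing CpG. Classification
uses the median of *raw* scores over covered CpGs: UMR when
n_cpgs > 32 and median < 0.20; LMR when n_cpgs < 32 and 0.20 ≤ median <
0.50. Both count inequalities are strict, so a region with exactly 32 CpGs
is deliberately unclassified, as is a median of exactly 0.20 (UMR side) or
0.50 (LMR side). The median is taken on raw rather than smoothed scores
because a region's "median methylation" is conventionally an observed
quantity; this is switchable. Replicate reproducibility is the conservative
reading of "present in all replicates": the base-pair intersection of
same-class regions across all replicates (≥ 1 bp chained overlap), with CpG
count and median recomputed on the intersected span from the first
replicate. The class label is carried from the inputs, not re-derived on the
(possibly smaller) intersection.

## DMR calling

For each of the four path contrasts of the 2-compartment × 2-stage design —
epithelium maturation, epithelium→fiber at the embryonic stage, fiber
maturation, and the direct embryonic-epithelium→newborn-fiber comparison —
a per-CpG statistic is computed over sites covered ≥ 4× in every replicate
of both groups:

    t = (mean_advanced − mean_early) / max(sd_local, sd_floor)

where the group means are over smoothed replicate scores, the pooled SD is
sqrt((sd_a² + sd_b²)/2) of within-group replicate SDs, `sd_local` averages
it over a 1 kb window, and `sd_floor` is the genome-wide 75th percentile of
`sd_local` — the flooring prevents division blow-ups at invariant sites.
Candidate DMRs are maximal runs of CpGs beyond the symmetric empirical
quantiles (0.025, 0.975) of the pooled t distribution, kept when they hold
≥ 3 CpGs and |mean smoothed difference| ≥ 0.10. `hyper`/`hypo` is the sign
of change from early to advanced; the area statistic is the sum of t over
the region. Reversing the group labels maps hyper↔hypo on identical
intervals (tested). A degenerate (constant) t distribution yields zero DMRs
with a warning.

Two scale caveats. First, quantile cutoffs assume truly differential CpGs
are a small fraction of the genome; the DMR benchmark keeps planted sites
under ~2.5 % per tail so the cutoff falls in the null of the t
distribution. Second, smoothing bleeds a boundary of up to about half a
window into the flanks, so called regions slightly overhang the true ones;
recovery is therefore scored with reciprocal-50 % overlap, the standard
interval-matching criterion.

## Feature annotation

From each transcript model: proximal promoter = 1 kb upstream of the TSS
(strand-aware), distal promoter = 1–5 kb upstream, 5′/3′ UTR = exonic bp
outside the CDS on the appropriate side, exon = coding exon bp (whole exons
for non-coding transcripts), intron = transcript bp not in exons;
intergenic is the genome complement of everything gene-linked. Transcripts
contribute independently (no collapsing); promoter windows are clipped to
chromosome bounds. The 1 kb proximal window is the annotation package
convention when only the 1–5 kb distal window is specified explicitly; it
is exposed as a parameter. A region is annotated with *every* feature it
overlaps by ≥ 1 bp and counted once per feature, so per-feature counts sum
to at least the region count.

## Shuffle enrichment

Observed per-feature counts are compared with `n_iterations` (default 20)
random placements of regions with the identical length multiset:
chromosome drawn ∝ placeable length, start uniform, optional exclusion set
honored by rejection (≤ 1000 tries), placements free to overlap one another
(the bedtools-shuffle convention). Enrichment is
log2((obs + ε)/(mean_shuffled + ε)) with ε = 0.5 to stabilize zero counts,
plus an empirical z. Under the null (regions produced by the shuffler
itself) |log2| stays below 0.3 for every feature occupying ≥ 5 % of the
genome at the tested scale.

## Chromatin integration

Stable open chromatin of a path is the bp intersection of the two endpoint
conditions' ATAC peaks minus DAR bp; opening/closing are the DAR intervals;
stable closed is the genome complement of stable open minus DAR bp. These
four states partition the genome exactly (bp conservation is asserted on
every construction) and overlapping opening/closing DARs are rejected as
ill-formed. Each DMR is assigned one state by majority bp with the fixed
tie order opening > closing > stable open > stable closed. A DMAR is the bp
intersection of an overlapping (DMR, DAR) pair, annotated with features and
genes; its DEG direction is the direction of an associated significant gene
(`up` preferred when genes disagree), `none` for associated-but-flat genes,
`no_gene` otherwise, with an identifier-space sanity check (> 50 % unmatched
gene ids is an error). Replicate ChIP peak sets are merged as bp supported
by both replicates — conservative and symmetric with the WGBS
reproducibility rule. TF peaks are open-associated iff they overlap ≥ 1 bp
of the merged ATAC set. DEG significance on read: padj < 0.05 with the
direction of the fold change (the customary reporting threshold; exposed).

## Metaplots

Center-anchored profiles bin signal within ± 5 kb of region midpoints
(bin 100 bp); boundary-anchored profiles keep fixed-width flank bins and
rescale the body to 50 bins. For methylomes the bin value is the
coverage-weighted mean of raw CpG scores; bins without covered CpGs are
missing, never zero — zero would masquerade as unmethylated. Aggregation is
a missing-aware column mean with per-bin counts. Group comparison over
shared peaks reports the ratio of group-level means and the Pearson
correlation of per-peak pairs, excluding (and counting) peaks without
signal.

## Synthetic data

The generator emulates the study design: 4 conditions (2 compartments × 2
stages) × 3 replicates, a 3 × 2 Mb genome, two-state CpG placement
(geometric spacing, mean 100 bp background / 10 bp inside islands), ~150
non-overlapping gene models with exon/CDS structure. Methylation is high
(0.85) in background, low (0.10) in constitutive promoter islands; planted
per-condition UMR islands (level 0.05), LMR islands (0.35), per-path DMR
regions (|Δ| = 0.4 at extra islands and at a subset of promoters that
demethylate along a path), and fiber-lineage regions that lose methylation
at both steps (appearing in both single-step paths and the direct
contrast). Counts are beta-binomial: coverage ~ Poisson(20), methylated
reads ~ BetaBinomial(coverage, μ, ρ = 0.05), plus a replicate-level
Gaussian jitter on μ (SD 0.02) — binomial noise alone would understate
replicate variance and make differential calling trivially easy. ATAC peaks
sit at promoters and random distal sites; DARs mirror 80 % of planted DMRs
(hypo ↔ opening, hyper ↔ closing); H3.3-style peaks cover expressed gene
bodies in two jittered replicates per compartment with a fiber bias; TF
peaks split between merged-ATAC space and deserts. The DEG table follows
the `deg_correlation` knob: genes whose promoters carry a hypo-opening DMAR
are upregulated with probability k (k = 1 gives a deterministic
demethylation→expression chain; k = 0 an independent null). The entire
dataset is a pure function of seed and config.

The DMR benchmark is a separate two-group scenario: a uniformly CpG-dense
genome (spacing 30 bp, ~460k CpGs over 14 Mb) with 200 planted 3 kb DMRs
(100 hyper / 100 hypo, |Δ| = 0.4, ≈100 CpGs each) — wide enough to be
resolvable against the smoothing window, sparse enough (≈2 % of CpGs per
tail) that quantile cutoffs stay in the null.

What passing these tests shows: the estimators, rules and interval algebra
do what they claim under a controlled generative model at desk scale. What
they do not show: robustness to real-data pathologies absent from the model
— bisulfite conversion failure, mapping bias, copy-number variation,
partially methylated domains, CpG-density confounding of shuffle
backgrounds, or genome-scale multiple-testing behaviour over ~20M CpGs.

## Problem sizes and determinism

Default scales were chosen so the full test suite and the acceptance script
each complete in well under a minute of compute on a single core: 3 × 2 Mb
study genome (~90k CpGs), 10,000 sampled CpGs for PCA, 2,000 regions × 20
iterations for enrichment calibration, and the 14 Mb benchmark genome for
DMR recovery. Every random step takes an explicit seed or Generator;
identical seeds give byte-identical outputs. The smoothing inner loop is
JIT-compiled with numba when available, with an identical pure-Python
fallback.

## Known limitations

- The segmenter is run-length on smoothed scores, not an HMM/FDR-based
  procedure; narrow LMRs below the smoothing window's resolution are not
  segmented end-to-end (classification of given regions is unaffected).
- Shuffle backgrounds are uniform over placeable positions; no GC/CpG
  matching.
- DMR boundaries overhang planted truth by up to ~half a smoothing window.
- `reproducible_regions` recomputes region statistics from one designated
  replicate rather than pooling replicates.
- Non-CpG contexts, hemimethylation and PMD detection are out of scope.
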