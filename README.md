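# methylscape

Methylome–chromatin integration for two-compartment differentiation studies.

Whole-genome bisulfite sequencing (WGBS) yields methylated/unmethylated read
counts at every CpG. In a differentiating tissue sampled as two compartments
(e.g. a proliferating epithelium and its postmitotic derivative) at two
developmental stages, the questions are: where is the genome unmethylated or
losing methylation, along which differentiation path, and how do those
regions line up with chromatin accessibility, histone-variant occupancy,
transcription-factor binding and gene expression? `methylscape` implements
that analysis chain as a tested Python library:

- **Methylome construction** — strand-collapsed per-CpG scores
  m/(m+u), BSmooth-style local smoothing (smallest centered window with
  ≥ 70 CpGs spanning ≥ 1 kb, tricube × coverage weights), random CpG
  sampling and sample-level PCA.
- **UMR/LMR segmentation** — runs of CpGs with smoothed score < 0.5, then
  classification on the raw-score median: unmethylated regions
  (> 32 CpGs, median < 20 %), low-methylated regions (< 32 CpGs, median
  20–50 %), and replicate-reproducible sets by 3-way bp intersection.
- **DMR calling** — per-CpG statistic t = (mean_adv − mean_early) / sd_pool,
  with the pooled replicate SD locally averaged (1 kb) and floored at its
  genome-wide 75th percentile; DMRs are runs of CpGs beyond the symmetric
  empirical quantile cutoffs (q = 0.025/0.975) with ≥ 3 CpGs and
  |Δmeth| ≥ 0.1, for the four path contrasts of a 2-compartment × 2-stage
  design.
- **Shuffle enrichment** — per-feature region counts vs 20 random
  placements of regions of the same number and sizes genome-wide;
  log2((obs + ½)/(mean + ½)) and an empirical z.
- **Annotation** — a seven-feature genome map (distal/proximal promoter,
  5′ UTR, exon, intron, 3′ UTR, intergenic) derived from gene models,
  counting a region once per feature it touches.
- **Integration** — peak specificity between compartments, chromatin states
  (opening/closing/stable open/stable closed — an exact genome partition),
  DMAR calling (DMR × DAR intersections), DEG association, TF-peak
  open/closed classification and peak × UMR/LMR cross-tabs.
- **Metaplots** — signal binned ± 5 kb around region centers (or scaled
  bodies), missing-aware aggregation, per-peak means and group comparison.
- **Synthetic data** — a generator with planted UMRs/LMRs/DMRs, ATAC
  peaks/DARs, replicate ChIP peaks, TF peaks and correlated DEG labels,
  with beta-binomial read noise; every stage is testable end to end
  without any external download.

## Worked example

`examples/02_feature_enrichment.py` segments UMRs from three synthetic
epithelium replicates and measures their feature enrichment against
20 shuffles:

```
feature            observed  shuffled    log2       z
distal_promoter          56      20.8    1.41     9.4
proximal_promoter       114      10.6    3.37    35.8
utr5                     48       6.4    2.81    19.2
exon                     37      35.4    0.06     0.2
intron                  114      48.4    1.23     9.0
utr3                      0       6.5   -3.81    -2.9
intergenic               25      87.5   -1.79    -8.5
```

Unmethylated regions pile up in promoters and 5′ UTRs (log2 ≈ 3.4 means
~10-fold over random placement) and are depleted from intergenic space —
the hallmark distribution of regulatory hypomethylation.
`examples/03_call_dmrs.py` recovers 40/40 planted DMRs
(sensitivity 1.00, precision 1.00 at reciprocal-50 % overlap), e.g.

```
example call: chr1:79686-83511 hypo, 148 CpGs, mean diff -0.31, area statistic -1727
```

a region losing methylation from group A to group B. The other examples
cover segmentation/reproducibility, chromatin-state integration with DEG
association, and TF-peak metaplots.

A thin CLI mirrors the library:
`methylscape simulate | smooth | segment | dmr | annotate | enrich | profile`
(see `methylscape --help`).

## Layout

```
src/methylscape/   library (core, intervalops, io, methylome, segmentation,
                   dmr, annotation, enrichment, integration, profiles,
                   synthetic, cli)
examples/          one narrative script per capability
tests/             pytest suite with brute-force/bitmap oracles
docs/methods.md    model, parameters, design choices, limitations
```
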