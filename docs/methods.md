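# Methods

## The statistic

`ecrscan` detects genomic regions in which point-like sites — differentially
expressed genes, or differentially methylated regions (DMRs) reduced to a
representative position — are statistically over-represented. Each
chromosome is tiled with sliding windows of width *w* (default 2 Mb)
advanced by step *s* (default 50 kb). For window *i* with site count
*c<sub>i</sub>*, the score is

&nbsp;&nbsp;&nbsp;&nbsp;*z<sub>i</sub>* = (*c<sub>i</sub>* − μ̂) / σ̂,&nbsp;&nbsp;&nbsp;&nbsp;*p<sub>i</sub>* = 1 − Φ(*z<sub>i</sub>*),

where μ̂ and σ̂ are the mean and standard deviation of the window counts
themselves — an *empirical* null, not a parametric Poisson/binomial model.
The test is one-sided: depleted windows are never significant. Windows
with *p* < α (default 0.05) that overlap or lie within `merge_gap`
(default 50 kb) of each other are merged transitively into clusters. A
cluster's reported p-value is the minimum constituent-window p, and is
labeled as such; its members are the site points inside its span.

Assumptions worth stating plainly:

- **The null is contaminated by the signal.** μ̂ and σ̂ include any enriched
  windows, which inflates σ̂ and makes the test conservative when strong
  clusters are present. This is inherent to the empirical-null design.
- **Sliding windows are correlated.** With *s* ≪ *w*, adjacent windows
  share most of their sites, so the fraction of significant windows at a
  given α is not the per-test error rate. Calibration is therefore checked
  on non-overlapping windows (step = width), where the achieved rate at
  α = 0.05 is ≈ 0.05–0.06 (counts are discrete, so exact attainment is not
  expected).
- **Sites are points.** Gene/DMR intervals are reduced to a representative
  point (midpoint by default, start as an option). The window dwarfs
  typical site spans, so this choice is second-order.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `window_size` | 2,000,000 | bp | the regional-co-regulation scale of interest (2–5 Mb) |
| `step` | 50,000 | bp | fine positioning of cluster boundaries |
| `alpha` | 0.05 | — | per-window one-sided level for routine scans |
| `merge_gap` | 50,000 | bp | merges consecutive significant windows (one step apart) |
| `null_scope` | `genome` | — | one global expectation of site density; `per_chromosome` covers the alternative reading |
| `sd_mode` | `sample` | — | n−1 sd, the common statistical default; `population` is a switch |
| `mt_correction` | `none` | — | raw p < α reproduces the historical procedure; Benjamini–Hochberg offered for modern use |

Window tiling keeps every window full-length: a chromosome shorter than
*w* gets a single window, and the last window is right-anchored at the
chromosome end instead of truncated. Truncated trailing windows would
systematically depress counts and distort the shared null. Windows with
zero counts stay in the null statistics; excluding them would inflate μ̂.

Degenerate inputs: if σ̂ = 0 within a scope (all counts equal, e.g. an
empty site set) every p is set to 1 and a `DegenerateNullWarning` is
raised; fewer than two windows in a scope is an error. Cluster ids are
assigned deterministically in genome order, and all outputs are written
in (chromosome-order, start) order, so identical inputs give
byte-identical files.

## Comparison operations

Background gene clusters — clusters called from the positions of *all*
annotated genes — capture the genome's inherent gene clumping.
Subtraction removes, whole (never trimmed), any target cluster sharing at
least 1 bp with a background cluster; the operation is idempotent. An
optional minimum reciprocal-overlap fraction (default 0) exists for
sensitivity analysis. The overlap matrix counts overlapping cluster
*pairs* for each pair of labeled sets (symmetric), with the diagonal
holding each set's cluster count; the alternative "rows with ≥1 partner"
definition coincides on sparse data but breaks symmetry, so pairs were
chosen. Site-in-cluster percentages are kept unrounded internally and
rounded half-away-from-zero for summary display.

## The synthetic-data generator

The generator emulates the statistical structure of the study inputs the
scan was designed for, at desk scale:

- a genome of 5 × 40 Mb chromosomes (200 Mb total);
- a background annotation of 3,000 genes (1 kb intervals), one third of
  them inside 20 non-overlapping clumps of 2–5 Mb — the inherent gene
  clustering of a mammalian genome;
- 776 DMRs (500 bp intervals), one quarter placed inside the gene clumps,
  mirroring the observed share of DMRs falling in clusters;
- optional planted regions whose DMR density is an exact fold over the
  uniform expectation: the region is topped up to
  round(fold · n · len/genome_len) sites, so the fold is exact by
  construction (fold = 1 is a no-op).

Category totals (clumped/uniform/planted) are allocated deterministically
by rounding rather than per-site coin flips, so they are exact and
testable; every site carries a provenance tag in the ground truth.

What the generator does **not** model: probe-level microarray or
MeDIP-chip noise, gene-length and GC biases, chromosome-specific gene
density, assembly gaps, or correlated site placement beyond the clump
structure. Passing recovery tests therefore demonstrate that the scan
statistics behave as designed on data with the assumed structure — not
that any particular biological dataset will yield particular clusters.

## Recovery evaluation and its stringency

A planted region is recovered when some called cluster reaches an
interval-Jaccard of at least `jaccard_min` (0.5 in the benchmarks) with
it. Geometry matters here: a cluster is a union of full-width windows, so
it always spans ≥ 2 Mb, and at permissive α the flanking windows that
half-cover an enriched region are themselves significant, extending the
merged span to ~4–5 Mb around a 2 Mb region and capping Jaccard near 0.4.
Localization benchmarks therefore run the scan at a fixed genome-wide
significance level, α = 5×10⁻⁸ (the conventional genome-wide threshold,
applied per window regardless of genome size). At that stringency only
windows covering most of the enriched region pass, the merged cluster
hugs the region (Jaccard ≈ 0.55–0.65), and a uniform 200 Mb genome yields
no clusters at all. Routine scans for over-representation keep the
permissive α = 0.05 default; the two settings serve different questions
(flagging candidate regions vs. localizing a known-scale signal).

## Problem sizes used in the checks

Null calibration uses 1,000 uniform sites on a 200 Mb single-chromosome
genome, 200 replicates; planted recovery uses the same background with a
2 Mb, 5-fold region, 100 replicates each for the planted and the
uniform-specificity arm; oracle equivalence uses 100 random instances of
≤ 20 Mb genomes with ≤ 300 sites against an exhaustive per-window count.
These sizes give stable means (Monte-Carlo s.e. of the calibration
fraction ≈ 0.001) while keeping the whole suite fast.

## Known limitations

- The min-p cluster p-value is not corrected for the number of merged
  windows or clusters; treat it as a ranking score, not an inferential p.
- The empirical null assumes a roughly homogeneous background density;
  strong genome-wide heterogeneity (e.g. chromosome-scale density shifts)
  is only partly absorbed by `null_scope="per_chromosome"`.
- Overlap counts are cluster-level; no site-level overlap statistics or
  permutation enrichment p-values are provided.
- Interval arithmetic is 0-based half-open throughout; abutting intervals
  do not overlap.
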