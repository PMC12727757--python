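# Methods

`epiredist` quantifies the genome-wide redistribution of a histone mark —
prototypically H3K9me3 — between a parental and a treated condition, together
with the 3D-genome consequences of losing megabase-scale heterochromatin
domains. This note documents the models, the parameters that matter, and the
choices made where the design was genuinely open.

## Track normalization

Binned tag counts are depth-normalized to CPM (`value * 1e6 / total mapped
reads`). Replicates are merged **stepwise**: a fold-left pairwise mean,
`m1 = r1; m_k = (m_{k-1} + r_k) / 2`. For three replicates this equals
`(r1 + r2 + 2*r3) / 4` — later replicates carry more weight, and replicate
order matters. This reproduces the semantics of merging coverage tracks
pairwise with a running mean; it is deliberately *not* the arithmetic mean,
and the package treats replicate order as part of the analysis definition.

**MS calibration.** When quantitative mass spectrometry provides the
genome-wide percentage `p` of histones carrying the mark, the CPM track is
rescaled by `factor = p * n_bins / sum(values)`, so the genome-wide mean of
the output equals `p` exactly (a conservation property tested to 1e-9
relative tolerance). Values are then capped at 100, because a bin cannot
exceed a 100% local modification frequency; the cap is applied *after*
scaling, so clipping deliberately breaks the mean identity on tracks with
extreme peaks.

**Input ratio.** The alternative chain is
`log2((chip/chip_total + eps) / (input/input_total + eps))` with
`eps = 1e-15`, which keeps every bin finite (a chip signal over an empty
input bin saturates at ~36.5 rather than infinity), optionally multiplied by
the MS percentage ("quantitative scaling") to put both conditions on a
mass-anchored scale. No minimum-input-coverage filter is applied before
clustering; the bins are used as-is.

**Peakiness** is the mean depth-normalized coverage of the top 1% most-covered
1-kb windows, after removing windows overlapping a blacklist by >= 1 bp. The
top count is `ceil(0.01 * n)`; the descending sort is stable, so ties at the
cutoff resolve deterministically by window order. Tracks finer than the
window size are re-binned by summation, only by exact integer factors —
anything else is an error rather than a silent interpolation.

## Redistribution clustering

Each 100-kb bin contributes a point `(x_i, y_i)` = (parental, treated)
quantitatively normalized signal. HDBSCAN (scikit-learn implementation)
clusters the 2-D cloud; the parameter mapping is `min_points` -> minimum
cluster size *and* minimum samples, `eps` -> cluster-selection epsilon in the
same units as the scaled signal. The full-genome-scale defaults
(`min_points = 1000`, `eps = 1000`) are only meaningful relative to
full-genome data; the desk-scale fixture uses `min_points = 25`, `eps = 5`,
matched to its ~400 bins and its signal scale of tens of units.

Exactly the two largest clusters are retained. Polarity is automatic and
testable: the cluster with the larger `mean(y - x)` is **cluster A** (gain),
the other **cluster B** (loss). Finding fewer than two clusters raises an
error that names the parameters; bins are never silently relabeled.

Consolidation converts labeled bins to intervals and merges same-cluster
intervals separated by <= 1 Mb (inclusive: a gap of exactly 1 Mb merges).
Afterwards every cluster-B region overlapping a cluster-A region by >= 1 bp
is removed whole — no trimming. Signal fractions per region set are prorated
by the overlapped fraction of each bin, so fractions over an exact partition
of the genome sum to 100.

## Metagene profiles

Protein-coding genes are filtered to the interquartile length band computed
from the input (linear-interpolation percentiles, the common "type 7"
definition); genes whose `[TSS - 2 kb, TES + 2 kb]` window overlaps another
gene body are dropped to avoid edge effects. Stratification: `n` seeded-random
zero-count genes form the silent group; among genes at or above 0.1 FPKM the
bottom and top `n` by FPKM form the low and high groups (`n = 2000` at
full-genome scale, smaller at fixture scale, with a warning when a pool is
short).

The scale-regions matrix has fixed flank columns (2 kb at 500-bp bins on each
side) and 40 body columns. Body rescaling uses coverage-weighted averaging of
the underlying step function over equal-length segments, which conserves the
gene-body mean exactly for any gene length (tested to 1e-6). Minus-strand
rows are column-reversed so column 0 is always the 5' end. Positions off the
chromosome end contribute zero ("missing data as zero"); all-zero rows are
dropped before aggregation ("skip zeros").

## Gene sets and shift counting

*Large enhancer domains*: replicate peak sets are intersected; peaks with
average normalized count strictly greater than 100 that overlap at least one
annotated enhancer are extended by 50 kb per side (clamped to chromosome
ends) and union-merged.

*Matched sets*: eligible genes are protein-coding, at least 1 FPKM at
baseline and inside the FPKM window (9–12 at full scale; the fixture uses
1–40 because a 200-gene genome puts few genes in a 3-FPKM-wide window).
In-domain genes are those overlapping the domains by >= 1 bp of gene body;
the control is an equal-size seeded sample of eligible genes outside the
domains, drawn once and recorded with its seed.

*Shift counting* is sign-based — up = log2FC > 0, down = < 0, zeros counted
separately — with a two-sided Wilcoxon rank-sum test between the two sets'
log2FC distributions. Significance-thresholded counting (|log2FC| and
adjusted p cutoffs) is available as an optional filter but is not the
default, because sign counts are what sum to the set size.

*Accessible CREs*: shared peaks (intersection of the two conditions) are
promoters if they overlap a strand-aware `[TSS - 1500, TSS + 500)` window,
and enhancers only if no part lies within +/- 3 kb of any TSS — the two
classes are constructed to be disjoint around promoters.

*Per-gene mark change*: prorated mean gene-body signal per condition,
`log2((s_treated + c) / (s_parental + c))` with pseudocount `c = 0.1` on the
MS-percent scale; loss means a negative value.

## Hi-C statistics

Matrices are per-chromosome (cis only), symmetric, with a bad-bin mask; any
cell touching a masked bin is excluded from every mean. O/E divides each
diagonal by its mean over unmasked cells — a deliberate simplification (no
smoothing) that is deterministic and adequate at fixture scale, and a
documented divergence from production Hi-C tooling. The compartment score is
the leading eigenvector of the Pearson correlation matrix of O/E, scaled by
the square root of its eigenvalue and sign-flipped to correlate non-negatively
with a phasing track (GC content in real data; at fixture scale the negated
planted-domain indicator, so positive = A).

**Saddle strength**: bins are ranked by score; `AA = mean O/E` over
off-diagonal cell pairs with both bins in the top 20%, `BB` with both in the
bottom 20%. The cross-compartment denominator has two supported readings,
because "the bottom 20% of A-B interactions" is ambiguous outside the tool
that produced it: the default `saddle-corner` mode uses the extreme-quantile
cross cells (top-20% vs bottom-20% bins); `global-bottom` takes the lowest
20% of all cross-sign cell values. Per-chromosome strengths are combined by
unweighted mean (a weighted option exists). Long-range cis contacts span
> 10 Mb; short-range 1 kb–10 Mb; sub-kilobase separations are excluded from
the denominator as ligation artifacts.

A caution discovered while validating the null: eigenvector scores *fitted on
a structureless matrix* overfit the same noise the saddle then averages, and
bias the strength below 1. Null checks therefore evaluate the statistic
either at an independent random ranking or at the planted partition.

## Loops

Loops live on a fixed calling grid (25 kb). Span is the anchor
midpoint-to-midpoint distance; long-range means strictly greater than 500 kb.
A parental long-range loop is *lost* when no treated long-range loop on the
same chromosome has both anchor starts within `tolerance_bins` grid bins
(default 0 — exact grid equality, since both sets come from the same fixed
grid). Enhancers overlapping a lost anchor by >= 1 bp are mapped to the
nearest protein-coding gene by gene-body distance (0 when overlapping;
ties to the smaller gene start; TSS-distance available via a flag), genes are
deduplicated, and their log2FC distribution is summarized by sign counts plus
a rank-sum test against all remaining genes.

## Foci arithmetic

Per-nucleus foci counts are multiplied by (mean reference nuclear area /
mean condition nuclear area), so conditions with larger nuclei are not
credited with more foci; the mean focus-to-center distance is divided by the
nuclear radius, making a boundary focus exactly 1 regardless of nucleus size.
Mean areas are computed per condition from the provided table unless explicit
values are supplied.

## Synthetic study conditions

The generator's defaults define the fixed study conditions: 2 chromosomes of
20 Mb; 5 genes/Mb with log-normal lengths (median 20 kb, sigma 0.6) and >= 4 kb
spacing; 25% of the genome in five 2-Mb heterochromatin domains, grid-aligned
to 100 kb and separated by >= 3 Mb so that 1-Mb consolidation cannot fuse
neighbouring planted domains; gene placement inside domains down-weighted
(bias 0.6) with 70% of in-domain genes silent — domains are gene-poor but not
gene-free, matching the thousands of silent genes real heterochromatin
domains contain. Parental domain enrichment is 8-fold; in the treated
condition domains collapse to background while gene bodies gain enrichment
proportional to `log(1 + FPKM)` (coefficient 0.5).

Counts follow the sequencing design being emulated: three biological
replicates per ChIP condition, each 2e6 tags, negative-binomial per bin
(dispersion 0.1; `poisson=True` gives the limiting case), pooled by
summation. The input control is a single library with Poisson counts on a
mappability-jittered flat profile (log-normal sd 0.05) — an input has no
immunoprecipitation-efficiency variance, and giving it the ChIP dispersion
would smear the two-condition scatter along the diagonal through the shared
denominator. MS percentages are the genome-wide means of the true per-bin
modification frequencies (5% per unenriched bin, capped at 100), averaged
over three noisy replicate measurements (sd 0.1 percentage points).

Contact maps: expected counts `60 * (d + 1)^-1` per cell, times
`(1 + contrast)` for same-compartment pairs (compartment = planted-domain
indicator at 100-kb bins; contrast 1.0 parental, 0.3 treated), times
`(1 + 2.0)` at planted loop-anchor pairs; Poisson-sampled upper triangle,
symmetrized. Twelve loops per chromosome are planted on the 25-kb grid in
non-domain territory with log-uniform spans (200 kb–6 Mb); 70% of the
long-range (> 500 kb) subset is dropped from the treated loop list, and an
enhancer is placed at every anchor center. Expression responses: genes
overlapping planted domains get mean +2 log2FC (domain loss de-represses
them), nearest genes of dropped-loop anchor enhancers get −1.5, everything
else 0, with Gaussian noise (sd 0.5) and BH-adjusted p-values from z-scores.

One master seed fans out through
`numpy.random.SeedSequence([master, component_index])` with fixed indices
(genome 0, tracks 1, contacts 2, expression 3), so each component is
independently reproducible.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: mappability and GC bias beyond a flat log-normal
jitter, copy-number variation, fragment-length effects, blacklist artifacts,
trans contacts, matrix balancing, replicate-specific batch effects, and any
coupling between expression noise and sequencing depth. Recovery results on
the fixture demonstrate correctness of the procedures under the stated model,
not power on any particular real dataset.

## Problem sizes and determinism

The shipped configuration analyses a 40-Mb genome in 400 100-kb bins, 200
genes, two 200x200 contact matrices per condition and ~24 loops; the full
pipeline runs in about a second and the whole validation suite in a few
minutes on one CPU. These sizes were chosen so every stage, including the
20-seed recovery sweeps, runs interactively. All floats are written in
shortest exact round-trip form, JSON is key-sorted, and no timestamps enter
any output, so two runs with the same config and seed produce byte-identical
manifests.

## Known limitations

- The HDBSCAN `eps`/`min_points` defaults at full-genome scale are recorded
  as-given; their effect depends on the absolute scale of the quantitative
  signal, so new datasets need a scale check before trusting the defaults.
- Whole-region cluster-B exclusion is aggressive by construction: a single
  stray cluster-A bin inside a loss domain removes the entire region. This
  faithfulness to the stated procedure makes the clustering step sensitive to
  per-bin outliers when track noise is high.
- The per-diagonal O/E estimator is unsmoothed; at very long separations with
  few cells per diagonal it is noisy, which mildly inflates the variance of
  saddle strengths on small matrices.
- Compartment scores use one eigenvector; genomes where the leading
  eigenvector tracks something other than compartments (e.g. arm-level
  effects) would need the usual manual eigenvector selection, which is not
  implemented.
- The pipeline's gene-set stage reuses the planted heterochromatin domains as
  the domain set for matched-set construction; with real data the large
  enhancer-domain builder (`build_large_enhancer_domains`) supplies that
  input instead.
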