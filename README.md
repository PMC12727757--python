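# epiredist

Quantitative detection of genome-wide **histone-mark redistribution** between
two conditions, built for the situation where a repressive mark
(prototypically H3K9me3) drains out of megabase-scale heterochromatin domains
and invades active chromatin. The package is aimed at computational
epigenomics practitioners who have binned coverage tracks, mass-spectrometry
(MS) global modification percentages, expression tables and (optionally)
Hi-C contact matrices and loop calls, and who want the full quantitative
analysis layer — normalization through domain calling to 3D-genome
statistics — as a tested, reusable library.

## What it computes

**MS-calibrated normalization.** Depth normalization to CPM, stepwise
replicate merging (`m_k = (m_{k-1} + r_k)/2`, so three replicates merge to
`(r1 + r2 + 2 r3)/4`), and MS calibration: with global modification
percentage *p*, the track is rescaled by `p · n_bins / Σv` so its
genome-wide mean equals *p* (then capped at 100). Alternatively
`log2((c/C + ε)/(i/I + ε))` over an input control (ε = 1e-15), times *p* for
quantitative scaling. The **peakiness** score — the mean coverage of the top
1% most-covered 1-kb windows, blacklist-excluded — summarizes how focal a
mark's distribution is.

**Redistribution domains.** Every 100-kb bin becomes a point
(x = parental, y = treated) in quantitatively normalized units; HDBSCAN
separates the two dominant behaviours, labeled **cluster A** (gain, larger
mean(y−x)) and **cluster B** (loss). Bins are consolidated into regions
(gaps ≤ 1 Mb merged; B regions touching A regions removed whole) and
per-region signal fractions quantify the redistribution.

**Metagene invasion profiles.** Interquartile-length, neighbour-free
protein-coding genes stratified into silent / low / high expression groups;
scale-regions matrices (2 kb flanks + 40 body columns at 500-bp bins,
strand-aware, body-mean conserving).

**Gene sets and shifts.** Large enhancer-cluster domains from replicated
peaks (count > 100, enhancer overlap, ± 50 kb extension); expression-matched
in-domain vs control gene sets; sign-based up/down counting with Wilcoxon
rank-sum comparison; accessible promoter/enhancer classification around
TSSs; per-gene mark log2 fold changes.

**Hi-C statistics.** O/E per-diagonal normalization; compartment scores from
the leading eigenvector of the O/E correlation matrix, sign-phased so
positive = A; saddle strength
`AA/AB` and `BB/AB` with the top/bottom 20% of bins; long-range (>10 Mb) vs
short-range cis fractions; A/B shift counts; long-range (>500 kb) loop
classification, lost-loop identification on the 25-kb grid, and the lost
anchor → enhancer → nearest-gene expression procedure.

**Foci arithmetic.** Area-ratio normalization of per-nucleus foci counts and
radius-normalized radial distances for immunofluorescence measurements.

A synthetic-epigenome generator (`epiredist.simulate`) plants all of the
above with known truth — domains, enrichment folds, loop drops, expression
responses — so every stage is testable end-to-end without any downloads.

## Worked example

`examples/` contains one narrative script per capability. The central one:

```bash
python examples/03_redistribution_clusters.py
```

```
cluster A (gain): 7 regions; cluster B (loss): 5 regions
Jaccard(cluster B, planted domains) = 1.000
 parental:  73.1% of signal in cluster B,  26.9% in cluster A
  treated:  22.8% of signal in cluster B,  77.2% in cluster A
```

The five consolidated loss regions coincide exactly with the five planted
2-Mb heterochromatin domains (Jaccard 1.0), and the signal fractions show the
redistribution: in the parental condition 73% of the mark lives in the loss
domains, in the treated condition only 23% — the mark has moved into the
gain regions. The Hi-C companion script prints the 3D consequences:

```bash
python examples/06_hic_compartments_and_loops.py
```

```
 parental: strength A-A = 2.33, B-B = 2.08, long-range cis fraction = 0.043
  treated: strength A-A = 1.51, B-B = 1.37, long-range cis fraction = 0.046
loops: 24 parental, 15 treated, 9 lost (> 500 kb)
lost-loop target genes: 18 down / 0 up (rank-sum p = 9.83e-12)
```

Compartment checkerboarding weakens (saddle strengths drop from ~2.2 to
~1.4), nine long-range loops disappear, and all 18 genes wired to the lost
anchors through their enhancers are down-regulated.

## Pipeline and CLI

The full chain — simulate → normalize → cluster → metagene → genesets → hic →
loops → report — runs from one config:

```bash
epiredist run --outdir out/ --seed 1
```

Outputs are plain text (bedGraph, BED, TSV, BEDPE, COO matrices, JSON stats)
plus a `manifest.json` with SHA-256 hashes; two runs with the same seed are
byte-identical. Subcommands `simulate`, `normalize`, `peakiness`, `cluster`
and `foci` expose individual stages; exit codes are 0 (ok), 2 (validation),
3 (stage failure).

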