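"""Bespoke gene-set constructions and expression-shift counting.

Covers four procedures used to link mark changes to expression: building
large enhancer-cluster domains from replicated peaks, constructing
expression-matched in-domain vs control gene sets, sign-based up/down shift
counting with a rank-sum comparison, classifying shared accessible regions
into promoters vs enhancers, and per-gene mark fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import BinnedTrack, GenomeLayout, GenomicsError, IntervalSet
from .tables import ExpressionDelta, GeneTable


@dataclass(frozen=True)
class MatchedGeneSets:
    in_domain: tuple[str, ...]
    control: tuple[str, ...]
    fpkm_window: tuple[float, float]
    seed: int


@dataclass(frozen=True)
class ShiftCount:
    n_up: int
    n_down: int
    n_zero: int
    stat: float
    pvalue: float

    @property
    def n(self) -> int:
        return self.n_up + self.n_down + self.n_zero


def intersect_replicate_peaks(peak_sets: list[IntervalSet]) -> IntervalSet:
    """Intersection of peak sets across replicates (sorted, merged)."""
    if len(peak_sets) < 2:
        raise GenomicsError("need at least two replicate peak sets")
    out = peak_sets[0].merge()
    for p in peak_sets[1:]:
        out = out.intersect(p)
    return out


def build_large_enhancer_domains(
    peaks: IntervalSet,
    avg_counts: np.ndarray,
    enhancers: IntervalSet,
    layout: GenomeLayout,
    extend_bp: int = 50_000,
    min_avg_count: float = 100.0,
) -> IntervalSet:
    """Large enhancer-cluster domains from replicate-intersected peaks.

    ``peaks`` is the replicate intersection (see
    :func:`intersect_replicate_peaks`) and ``avg_counts`` the replicate-mean
    normalized read count aligned to its records.  Peaks are kept when the
    average count strictly exceeds ``min_avg_count`` AND they overlap at least
    one annotated enhancer; survivors are extended by ``extend_bp`` on each
    side (clamped to chromosome ends) and union-merged.
    """
    avg_counts = np.asarray(avg_counts, dtype=float)
    if avg_counts.shape != (len(peaks),):
        raise GenomicsError("avg_counts must align with the intersected peaks")
    keep = (avg_counts > min_avg_count) & peaks.overlaps_any(enhancers)
    if not keep.any():
        warnings.warn("no peaks survive the count/enhancer filters")
        return IntervalSet.empty()
    df = peaks.df[keep].copy()
    lengths = layout.lengths
    df["start"] = np.maximum(df["start"] - extend_bp, 0)
    df["end"] = [
        min(e + extend_bp, lengths[c]) for c, e in zip(df["chrom"], df["end"])
    ]
    return IntervalSet(df).merge()


def build_matched_gene_sets(
    genes: GeneTable,
    domains: IntervalSet,
    fpkm_lo: float = 9.0,
    fpkm_hi: float = 12.0,
    baseline_min: float = 1.0,
    seed: int = 0,
) -> MatchedGeneSets:
    """Expression-matched in-domain vs randomized control gene sets.

    Eligible genes are protein-coding with baseline FPKM >= ``baseline_min``
    and inside [fpkm_lo, fpkm_hi].  The in-domain set is every eligible gene
    overlapping ``domains`` (>=1 bp of gene body); the control is an
    equal-size seeded sample (without replacement) of eligible genes that do
    not overlap the domains.
    """
    pc = genes.protein_coding()
    fpkm = pc.df["baseline_fpkm"]
    eligible = pc.df[
        (fpkm >= baseline_min) & (fpkm >= fpkm_lo) & (fpkm <= fpkm_hi)
    ]
    if eligible.empty:
        raise GenomicsError("no eligible genes in the FPKM window")
    esub = GeneTable(eligible.reset_index(drop=True))
    hit = esub.intervals().overlaps_any(domains)
    in_ids = tuple(esub.df["gene_id"][hit])
    if not in_ids:
        raise GenomicsError("no eligible genes overlap the domains")
    pool = np.sort(esub.df["gene_id"][~hit].values)
    if len(pool) < len(in_ids):
        raise GenomicsError(
            f"control pool ({len(pool)}) smaller than in-domain set ({len(in_ids)})"
        )
    rng = np.random.default_rng(seed)
    control = tuple(sorted(rng.choice(pool, size=len(in_ids), replace=False)))
    return MatchedGeneSets(in_ids, control, (fpkm_lo, fpkm_hi), seed)


def count_expression_shifts(
    set_a, set_b, deltas: ExpressionDelta
) -> tuple[ShiftCount, ShiftCount]:
    """Sign-based up/down/zero counts per set plus a rank-sum comparison.

    Genes lacking an expression record are excluded with a warning.  The
    two-sided Wilcoxon rank-sum test compares the log2FC distributions of the
    two sets; the same statistic is recorded in both results.
    """
    counts = []
    lfcs = []
    for ids in (set_a, set_b):
        ids = list(ids)
        if not ids:
            raise GenomicsError("empty gene set")
        expr = deltas.lookup(ids)
        if len(expr) < len(ids):
            warnings.warn(
                f"{len(ids) - len(expr)} gene(s) lack expression records; excluded"
            )
        lfcs.append(expr["log2fc"].values)
    stat, p = stats.ranksums(lfcs[0], lfcs[1])
    for lfc in lfcs:
        counts.append(
            ShiftCount(
                n_up=int((lfc > 0).sum()),
                n_down=int((lfc < 0).sum()),
                n_zero=int((lfc == 0).sum()),
                stat=float(stat),
                pvalue=float(p),
            )
        )
    return counts[0], counts[1]


def classify_accessible_cres(
    atac_condition1: IntervalSet,
    atac_condition2: IntervalSet,
    genes: GeneTable,
    promoter_upstream: int = 1500,
    promoter_downstream: int = 500,
    tss_exclusion: int = 3000,
) -> tuple[IntervalSet, IntervalSet]:
    """Split shared accessible peaks into (enhancers, promoters).

    Shared peaks are the intersection of the two conditions' peak sets.
    Promoter windows are strand-aware [TSS - 1500, TSS + 500); a shared peak
    overlapping one is an accessible promoter.  Accessible enhancers are
    shared peaks with no part within +/- ``tss_exclusion`` of any TSS.
    """
    shared = atac_condition1.intersect(atac_condition2)
    tss = genes.tss()
    prom_rows, excl_rows = [], []
    for (_, t), strand in zip(tss.iterrows(), genes.df["strand"]):
        pos = int(t["tss"])
        if strand == "-":
            prom_rows.append((t["chrom"], pos - promoter_downstream + 1,
                              pos + promoter_upstream + 1))
        else:
            prom_rows.append((t["chrom"], pos - promoter_upstream,
                              pos + promoter_downstream))
        excl_rows.append((t["chrom"], pos - tss_exclusion, pos + tss_exclusion + 1))
    prom_rows = [(c, max(s, 0), e) for c, s, e in prom_rows]
    excl_rows = [(c, max(s, 0), e) for c, s, e in excl_rows]
    prom_windows = IntervalSet.from_records(prom_rows)
    excl_windows = IntervalSet.from_records(excl_rows)
    promoters = shared.overlap_filter(prom_windows)
    enhancers = shared.overlap_filter(excl_windows, invert=True)
    return enhancers, promoters


def gene_mark_change(
    parental_track: BinnedTrack,
    treated_track: BinnedTrack,
    genes: GeneTable,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Per-gene log2 fold change of gene-body mark signal.

    For each gene: s = prorated mean signal over the gene body per condition;
    log2FC = log2((s_treated + c) / (s_parental + c)).  Loss <=> value < 0.
    """
    if not parental_track.same_grid(treated_track):
        raise GenomicsError("tracks must share layout and bin size")
    if parental_track.units != treated_track.units:
        raise GenomicsError("tracks must share units")
    genes.intervals().check_in_layout(parental_track.layout)
    rows = []
    for _, g in genes.df.iterrows():
        sp = parental_track.mean_over(g["chrom"], int(g["start"]), int(g["end"]))
        st = treated_track.mean_over(g["chrom"], int(g["start"]), int(g["end"]))
        rows.append(
            {"gene_id": g["gene_id"],
             "log2fc": float(np.log2((st + pseudocount) / (sp + pseudocount)))}
        )
    return pd.DataFrame(rows)
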