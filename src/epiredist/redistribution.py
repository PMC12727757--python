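"""Detection of histone-mark redistribution domains from binned signal.

Two quantitatively normalized tracks (parental and treated, typically
log2-ratio-over-input times the MS percentage, in 100-kb bins) are viewed as a
2-D point cloud, one point per genomic bin.  Density-based clustering splits
the bins into the two dominant behaviours: cluster A — bins that *gain* the
mark in the treated condition — and cluster B — bins that *lose* it, which at
megabase scale correspond to collapsing heterochromatic domains.  Labeled bins
are consolidated into merged regions and per-region signal fractions quantify
the redistribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN

from .genome import BinnedTrack, GenomeLayout, GenomicsError, IntervalSet


@dataclass(frozen=True)
class ClusterParams:
    """Density-clustering and consolidation parameters.

    ``min_points`` maps to HDBSCAN's minimum cluster size and minimum samples;
    ``eps`` to its cluster-selection epsilon, in the same units as the
    quantitatively scaled signal.  The defaults are full-genome-scale values;
    small fixtures need proportionally smaller ``min_points`` and an ``eps``
    matched to their signal scale.
    """

    min_points: int = 1000
    eps: float = 1000.0
    merge_gap: int = 1_000_000
    genic_cover_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.min_points < 2:
            raise GenomicsError("min_points must be >= 2")
        if self.eps <= 0:
            raise GenomicsError("eps must be > 0")
        if self.merge_gap < 0:
            raise GenomicsError("merge_gap must be >= 0")


@dataclass
class RedistributionClusters:
    """Per-bin A/B/noise labels plus consolidated gain/loss regions."""

    layout: GenomeLayout
    bin_size: int
    labels: np.ndarray  # per bin: "A", "B" or "noise"
    regions_a: IntervalSet = field(default_factory=IntervalSet.empty)
    regions_b: IntervalSet = field(default_factory=IntervalSet.empty)
    polarity: str = "A gains"


def bin_counts(
    intervals: IntervalSet, layout: GenomeLayout, bin_size: int = 100_000
) -> BinnedTrack:
    """Count, per genomic bin, the records overlapping it.

    A record straddling a bin boundary increments every bin it touches.
    """
    intervals.check_in_layout(layout)
    values = np.zeros(layout.total_bins(bin_size), dtype=np.float64)
    offsets = layout.bin_offsets(bin_size)
    for _, r in intervals.df.iterrows():
        b0 = r["start"] // bin_size
        b1 = (r["end"] - 1) // bin_size
        off = offsets[r["chrom"]]
        values[off + b0: off + b1 + 1] += 1
    return BinnedTrack(layout, bin_size, values, "count")


def annotate_bins(
    layout: GenomeLayout,
    bin_size: int,
    genes: IntervalSet,
    genic_cover_threshold: float = 0.5,
) -> np.ndarray:
    """Label each bin 'genic' or 'intergenic'.

    A bin is genic iff the union of gene bodies covers strictly more than
    ``genic_cover_threshold`` of it.
    """
    probe = BinnedTrack(
        layout, bin_size, np.zeros(layout.total_bins(bin_size)), "count"
    )
    frac = probe.region_weights(genes.merge())
    return np.where(frac > genic_cover_threshold, "genic", "intergenic")


def cluster_redistribution(
    x: BinnedTrack, y: BinnedTrack, params: ClusterParams
) -> RedistributionClusters:
    """Density-cluster bins on the 2-D scatter (parental x, treated y).

    Exactly the two largest clusters are retained; the one with the greater
    mean(y - x) is labeled A (gain), the other B (loss); everything else is
    noise.  Fewer than two clusters is an error — parameters must be adjusted
    explicitly, never silently relabeled.
    """
    if not x.same_grid(y):
        raise GenomicsError("parental and treated tracks must share the bin grid")
    pts = np.column_stack([x.values, y.values])
    model = HDBSCAN(
        min_cluster_size=params.min_points,
        min_samples=params.min_points,
        cluster_selection_epsilon=params.eps,
        copy=True,
    )
    raw = model.fit_predict(pts)
    ids, sizes = np.unique(raw[raw >= 0], return_counts=True)
    if len(ids) < 2:
        raise GenomicsError(
            f"found {len(ids)} cluster(s); need 2 — adjust min_points/eps "
            f"(min_points={params.min_points}, eps={params.eps})"
        )
    top2 = ids[np.argsort(sizes, kind="stable")[::-1][:2]]
    diff = y.values - x.values
    means = {cid: float(diff[raw == cid].mean()) for cid in top2}
    a_id = max(top2, key=lambda cid: (means[cid], -cid))
    b_id = top2[0] if top2[1] == a_id else top2[1]
    labels = np.full(len(raw), "noise", dtype=object)
    labels[raw == a_id] = "A"
    labels[raw == b_id] = "B"
    return RedistributionClusters(x.layout, x.bin_size, labels)


def _bins_to_regions(
    mask: np.ndarray, layout: GenomeLayout, bin_size: int, merge_gap: int
) -> IntervalSet:
    rows = []
    offsets = layout.bin_offsets(bin_size)
    n_bins = layout.n_bins(bin_size)
    for chrom in layout.chrom_names:
        off, n = offsets[chrom], n_bins[chrom]
        length = layout.lengths[chrom]
        idx = np.flatnonzero(mask[off: off + n])
        if len(idx) == 0:
            continue
        start = int(idx[0]) * bin_size
        prev = int(idx[0])
        for b in idx[1:]:
            gap = (int(b) - prev - 1) * bin_size
            if gap > merge_gap:
                rows.append((chrom, start, min((prev + 1) * bin_size, length)))
                start = int(b) * bin_size
            prev = int(b)
        rows.append((chrom, start, min((prev + 1) * bin_size, length)))
    return IntervalSet.from_records(rows)


def consolidate_clusters(
    clusters: RedistributionClusters, params: ClusterParams
) -> RedistributionClusters:
    """Merge labeled bins into regions; drop B regions touching any A region.

    Bins of one cluster separated by a gap <= ``merge_gap`` (inclusive) are
    merged into one region.  Afterwards every cluster-B region overlapping a
    cluster-A region by >=1 bp is removed whole (no trimming).
    """
    layout, w = clusters.layout, clusters.bin_size
    regions_a = _bins_to_regions(clusters.labels == "A", layout, w, params.merge_gap)
    regions_b = _bins_to_regions(clusters.labels == "B", layout, w, params.merge_gap)
    if len(regions_b) and len(regions_a):
        regions_b = regions_b.overlap_filter(regions_a, invert=True)
    return RedistributionClusters(
        layout, w, clusters.labels, regions_a, regions_b, clusters.polarity
    )


def signal_fraction_in_regions(track: BinnedTrack, regions: IntervalSet) -> float:
    """Percent of total signal falling in ``regions`` (bins prorated)."""
    if np.any(track.values < 0):
        raise GenomicsError("signal fractions require non-negative values")
    total = float(track.values.sum())
    if total <= 0:
        raise GenomicsError("zero total signal")
    w = track.region_weights(regions)
    return 100.0 * float((track.values * w).sum()) / total
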