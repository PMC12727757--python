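"""Coverage-track normalization chain and the peakiness statistic.

The chain mirrors quantitative ChIP-seq practice when a mass-spectrometry (MS)
measurement of the global modification percentage is available:

1. depth normalization to counts-per-million (CPM);
2. stepwise pairwise merging of replicates (fold-left running mean);
3. MS calibration: rescale so the genome-wide mean equals the MS percentage,
   then clip at 100 (a bin cannot exceed 100% local modification frequency);
4. alternatively, log2 ratio over an input control with a tiny pseudocount,
   optionally multiplied by the MS percentage ("quantitative" scaling).

The peakiness score summarizes how focal a mark's distribution is: the mean
depth-normalized coverage of the top 1% most-covered 1-kb windows, after
removing blacklisted windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import BinnedTrack, GenomicsError, IntervalSet


@dataclass(frozen=True)
class NormalizationParams:
    pseudocount: float = 1e-15
    clip_cap: float = 100.0
    peakiness_top_fraction: float = 0.01
    peakiness_bin: int = 1000

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise GenomicsError("pseudocount must be > 0")
        if not 0 < self.peakiness_top_fraction <= 1:
            raise GenomicsError("peakiness_top_fraction must be in (0, 1]")
        if self.clip_cap <= 0:
            raise GenomicsError("clip_cap must be > 0")


DEFAULT_PARAMS = NormalizationParams()


def depth_normalize(track: BinnedTrack, total_mapped_reads: float) -> BinnedTrack:
    """Counts -> CPM: value * 1e6 / total mapped reads."""
    if total_mapped_reads <= 0:
        raise GenomicsError("total_mapped_reads must be > 0")
    return track.copy_with(track.values * 1e6 / total_mapped_reads, units="cpm")


def merge_replicates_stepwise(tracks: list[BinnedTrack]) -> BinnedTrack:
    """Fold-left pairwise mean: m1 = r1; m_k = (m_{k-1} + r_k) / 2.

    For three replicates this is (r1 + r2 + 2*r3) / 4, i.e. later replicates
    carry more weight — deliberately NOT the arithmetic mean, matching the
    stepwise pairwise-merge convention.  Replicate order therefore matters.
    """
    if not tracks:
        raise GenomicsError("need at least one replicate")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_grid(t) or t.units != first.units:
            raise GenomicsError("replicates must share layout, bin size and units")
    merged = first.values.copy()
    for t in tracks[1:]:
        merged = (merged + t.values) / 2.0
    return first.copy_with(merged)


def ms_calibrate(
    track: BinnedTrack, pct: float, params: NormalizationParams = DEFAULT_PARAMS
) -> BinnedTrack:
    """Rescale so the genome-wide mean equals the MS percentage, then clip.

    factor = pct * n_bins / sum(values); before clipping mean(out) == pct
    exactly.  Bins above ``clip_cap`` (default 100) are set to the cap, which
    reads as 100% local modification frequency.
    """
    if not 0 <= pct <= 100:
        raise GenomicsError("MS percentage must lie in [0, 100]")
    total = float(track.values.sum())
    if total <= 0:
        raise GenomicsError("cannot MS-calibrate an all-zero track")
    factor = pct * len(track.values) / total
    out = np.minimum(track.values * factor, params.clip_cap)
    return track.copy_with(out, units="ms_percent")


def input_log2_ratio(
    chip: BinnedTrack,
    chip_total: float,
    input_track: BinnedTrack,
    input_total: float,
    params: NormalizationParams = DEFAULT_PARAMS,
) -> BinnedTrack:
    """log2((chip/chip_total + eps) / (input/input_total + eps)) per bin."""
    if chip_total <= 0 or input_total <= 0:
        raise GenomicsError("read totals must be > 0")
    if not chip.same_grid(input_track):
        raise GenomicsError("chip and input tracks must share layout and bin size")
    eps = params.pseudocount
    num = chip.values / chip_total + eps
    den = input_track.values / input_total + eps
    return chip.copy_with(np.log2(num / den), units="log2ratio")


def quantitative_scale(track: BinnedTrack, pct: float) -> BinnedTrack:
    """Multiply a log2-ratio track by the genome-wide MS percentage."""
    return track.copy_with(track.values * pct)


def rebin_sum(track: BinnedTrack, new_bin: int) -> BinnedTrack:
    """Re-bin by summation; only exact integer factors are allowed."""
    if new_bin == track.bin_size:
        return track
    if new_bin < track.bin_size or new_bin % track.bin_size:
        raise GenomicsError(
            f"can only re-bin by an exact integer factor "
            f"({track.bin_size} -> {new_bin})"
        )
    factor = new_bin // track.bin_size
    out = np.zeros(track.layout.total_bins(new_bin), dtype=np.float64)
    old_off = track.layout.bin_offsets(track.bin_size)
    new_off = track.layout.bin_offsets(new_bin)
    old_n = track.layout.n_bins(track.bin_size)
    new_n = track.layout.n_bins(new_bin)
    for chrom in track.layout.chrom_names:
        vals = track.values[old_off[chrom]: old_off[chrom] + old_n[chrom]]
        for j in range(new_n[chrom]):
            out[new_off[chrom] + j] = vals[j * factor: (j + 1) * factor].sum()
    return BinnedTrack(track.layout, new_bin, out, track.units)


def peakiness(
    track: BinnedTrack,
    blacklist: IntervalSet | None = None,
    params: NormalizationParams = DEFAULT_PARAMS,
) -> float:
    """Mean coverage of the top 1% most-covered 1-kb windows.

    Windows overlapping the blacklist by >=1 bp are removed first.  The top
    count is ceil(top_fraction * n_remaining); the sort is stable so ties at
    the cutoff are resolved deterministically by window order.
    """
    if track.bin_size != params.peakiness_bin:
        track = rebin_sum(track, params.peakiness_bin)
    values = track.values
    if blacklist is not None and len(blacklist) > 0:
        hit = track.bin_intervals().overlaps_any(blacklist)
        values = values[~hit]
    n = len(values)
    if n == 0:
        raise GenomicsError("no windows left after blacklisting")
    k = math.ceil(params.peakiness_top_fraction * n)
    top = np.sort(values, kind="stable")[::-1][:k]
    return float(top.mean())
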