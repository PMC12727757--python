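"""Shared genomic data model: genome layout, interval sets, binned tracks.

All coordinates are 0-based half-open throughout the package; conversion from
1-based conventions (GTF) happens only at the I/O boundary.  Chromosome order
is always the order declared in :class:`GenomeLayout`, never lexicographic, so
that bin indexing is stable across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

VALID_UNITS = ("count", "cpm", "ms_percent", "log2ratio")

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


class GenomicsError(ValueError):
    """Base error for malformed genomic inputs."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths defining the coordinate system."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise GenomicsError("chrom_names and chrom_lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise GenomicsError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise GenomicsError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(d.keys()), tuple(int(v) for v in d.values()))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise GenomicsError(f"unknown chromosome: {chrom!r}") from None

    def n_bins(self, bin_size: int) -> dict[str, int]:
        """Bins per chromosome: ceil(length / bin_size)."""
        return {c: math.ceil(l / bin_size) for c, l in self.lengths.items()}

    def total_bins(self, bin_size: int) -> int:
        return sum(self.n_bins(bin_size).values())

    def bin_offsets(self, bin_size: int) -> dict[str, int]:
        """Offset of each chromosome's first bin in the concatenated vector."""
        offsets, acc = {}, 0
        for c, n in self.n_bins(bin_size).items():
            offsets[c] = acc
            acc += n
        return offsets

    def bins(self, bin_size: int) -> "IntervalSet":
        """All genomic bins, in vector order, clipped to chromosome ends."""
        rows = []
        for c, l in self.lengths.items():
            starts = np.arange(0, l, bin_size, dtype=np.int64)
            ends = np.minimum(starts + bin_size, l)
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        return IntervalSet(pd.concat(rows, ignore_index=True))


class IntervalSet:
    """Immutable-by-convention set of genomic intervals (0-based half-open).

    Backed by a pandas DataFrame with columns chrom/start/end and optional
    name/score/strand.  Set algebra delegates to pyranges; outputs are sorted
    deterministically by (chrom, start, end, name).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise GenomicsError(f"IntervalSet requires column {col!r}")
        for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        df["strand"] = df["strand"].astype(str)
        bad = df["start"] >= df["end"]
        if bad.any():
            i = int(np.argmax(bad.values))
            raise GenomicsError(
                f"interval with start >= end at record {i}: "
                f"{df.iloc[i]['chrom']}:{df.iloc[i]['start']}-{df.iloc[i]['end']}"
            )
        if not set(df["strand"].unique()) <= {"+", "-", "."}:
            raise GenomicsError("strand must be one of +, -, .")
        self.df = df[_BED_COLS].reset_index(drop=True)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "IntervalSet":
        """Records of (chrom, start, end[, name[, score[, strand]]])."""
        rows = []
        for r in records:
            r = tuple(r)
            row = dict(zip(_BED_COLS, r + (".", 0.0, ".")[len(r) - 3:]))
            rows.append(row)
        if not rows:
            return cls.empty()
        return cls(pd.DataFrame(rows))

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(
            pd.DataFrame(
                {
                    "chrom": pd.Series(dtype=str),
                    "start": pd.Series(dtype=np.int64),
                    "end": pd.Series(dtype=np.int64),
                }
            )
        )

    # -- basics -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a, b = self.sorted().df, other.sorted().df
        return a.equals(b)

    @property
    def total_bp(self) -> int:
        """Total covered bp after internal union-merge."""
        m = self.merge()
        return int((m.df["end"] - m.df["start"]).sum())

    def sorted(self, layout: GenomeLayout | None = None) -> "IntervalSet":
        df = self.df.copy()
        if layout is not None:
            order = {c: i for i, c in enumerate(layout.chrom_names)}
            unknown = set(df["chrom"]) - set(order)
            if unknown:
                raise GenomicsError(f"unknown chromosomes: {sorted(unknown)}")
            df["_c"] = df["chrom"].map(order)
        else:
            df["_c"] = df["chrom"]
        df = df.sort_values(["_c", "start", "end", "name"], kind="mergesort")
        return IntervalSet(df.drop(columns="_c").reset_index(drop=True))

    def check_in_layout(self, layout: GenomeLayout) -> None:
        lengths = layout.lengths
        for _, row in self.df.iterrows():
            if row["chrom"] not in lengths:
                raise GenomicsError(f"unknown chromosome: {row['chrom']!r}")
            if row["end"] > lengths[row["chrom"]]:
                raise GenomicsError(
                    f"interval {row['chrom']}:{row['start']}-{row['end']} "
                    f"exceeds chromosome length {lengths[row['chrom']]}"
                )

    # -- pyranges bridge --------------------------------------------------
    def _pr(self) -> pr.PyRanges:
        df = self.df.rename(
            columns={"chrom": "Chromosome", "start": "Start", "end": "End"}
        )
        return pr.PyRanges(df[["Chromosome", "Start", "End"]])

    @staticmethod
    def _from_pr(g: pr.PyRanges) -> "IntervalSet":
        df = g.df
        if df.empty:
            return IntervalSet.empty()
        df = df.rename(
            columns={"Chromosome": "chrom", "Start": "start", "End": "end"}
        )
        return IntervalSet(df[["chrom", "start", "end"]]).sorted()

    # -- set algebra ------------------------------------------------------
    def merge(self) -> "IntervalSet":
        """Union-merge: sorted, non-overlapping cover of the same bp."""
        if len(self) == 0:
            return IntervalSet.empty()
        return self._from_pr(self._pr().merge())

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        if len(self) == 0 or len(other) == 0:
            return IntervalSet.empty()
        return self._from_pr(self._pr().merge().intersect(other._pr().merge()))

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        if len(self) == 0:
            return IntervalSet.empty()
        if len(other) == 0:
            return self.merge()
        return self._from_pr(self._pr().merge().subtract(other._pr()))

    def complement(self, layout: GenomeLayout) -> "IntervalSet":
        self.check_in_layout(layout)
        rows = []
        merged = self.merge().df
        for chrom, length in layout.lengths.items():
            sub = merged[merged["chrom"] == chrom]
            prev = 0
            for _, r in sub.iterrows():
                if r["start"] > prev:
                    rows.append((chrom, prev, r["start"]))
                prev = max(prev, r["end"])
            if prev < length:
                rows.append((chrom, prev, length))
        return IntervalSet.from_records(rows)

    def overlap_filter(
        self, other: "IntervalSet", invert: bool = False
    ) -> "IntervalSet":
        """Keep records overlapping (>=1 bp) any interval of ``other``."""
        hits = self.overlaps_any(other)
        keep = ~hits if invert else hits
        return IntervalSet(self.df[keep].reset_index(drop=True))

    def overlaps_any(self, other: "IntervalSet") -> np.ndarray:
        """Boolean per record: overlaps >=1 bp with ``other``."""
        out = np.zeros(len(self), dtype=bool)
        if len(self) == 0 or len(other) == 0:
            return out
        om = other.merge().df
        for chrom, grp in self.df.groupby("chrom", sort=False):
            o = om[om["chrom"] == chrom]
            if o.empty:
                continue
            # merged intervals are disjoint & sorted: the only candidate for a
            # query [s, e) is the last interval starting before e
            starts = o["start"].values
            ends = o["end"].values
            j = np.searchsorted(starts, grp["end"].values, side="left") - 1
            hit = (j >= 0) & (ends[np.maximum(j, 0)] > grp["start"].values)
            out[grp.index] = hit
        return out

    def overlap_bp(self, other: "IntervalSet") -> np.ndarray:
        """Per-record bp of overlap with the union of ``other``."""
        out = np.zeros(len(self), dtype=np.int64)
        if len(self) == 0 or len(other) == 0:
            return out
        om = other.merge().df
        for chrom, grp in self.df.groupby("chrom", sort=False):
            o = om[om["chrom"] == chrom]
            if o.empty:
                continue
            starts = o["start"].values
            ends = o["end"].values
            for idx, s, e in zip(grp.index, grp["start"].values, grp["end"].values):
                out[idx] = int(
                    np.sum(np.clip(np.minimum(ends, e) - np.maximum(starts, s), 0, None))
                )
        return out

    def jaccard(self, other: "IntervalSet") -> float:
        """Jaccard index on covered bp."""
        inter = self.intersect(other).total_bp
        union = self.total_bp + other.total_bp - inter
        return inter / union if union else 1.0


@dataclass
class BinnedTrack:
    """Fixed-bin genome-wide signal vector (concatenated in layout order)."""

    layout: GenomeLayout
    bin_size: int
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.units not in VALID_UNITS:
            raise GenomicsError(f"units must be one of {VALID_UNITS}")
        n = self.layout.total_bins(self.bin_size)
        if self.values.shape != (n,):
            raise GenomicsError(
                f"expected {n} bins for bin_size={self.bin_size}, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise GenomicsError("track values must be finite")
        if self.units in ("count", "cpm", "ms_percent") and np.any(self.values < 0):
            raise GenomicsError(f"{self.units} values must be >= 0")

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "BinnedTrack":
        return BinnedTrack(self.layout, self.bin_size, values, units or self.units)

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.layout == other.layout and self.bin_size == other.bin_size
        )

    def bin_intervals(self) -> IntervalSet:
        return self.layout.bins(self.bin_size)

    def region_weights(self, regions: IntervalSet) -> np.ndarray:
        """Fraction of each bin covered by the union of ``regions`` (0..1)."""
        w = np.zeros(len(self.values), dtype=np.float64)
        if len(regions) == 0:
            return w
        merged = regions.merge().df
        offsets = self.layout.bin_offsets(self.bin_size)
        lengths = self.layout.lengths
        for _, r in merged.iterrows():
            chrom = r["chrom"]
            if chrom not in offsets:
                raise GenomicsError(f"unknown chromosome: {chrom!r}")
            s, e = int(r["start"]), min(int(r["end"]), lengths[chrom])
            b0 = s // self.bin_size
            b1 = (e - 1) // self.bin_size
            for b in range(b0, b1 + 1):
                bs = b * self.bin_size
                be = min(bs + self.bin_size, lengths[chrom])
                ov = min(be, e) - max(bs, s)
                if ov > 0:
                    w[offsets[chrom] + b] += ov / (be - bs)
        return np.clip(w, 0.0, 1.0)

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean signal over [start, end); out-of-range bp -> 0."""
        length = self.layout.lengths.get(chrom)
        if length is None:
            raise GenomicsError(f"unknown chromosome: {chrom!r}")
        if end <= start:
            raise GenomicsError("end must exceed start")
        off = self.layout.bin_offsets(self.bin_size)[chrom]
        total = 0.0
        s_in, e_in = max(start, 0), min(end, length)
        if e_in > s_in:
            b0, b1 = s_in // self.bin_size, (e_in - 1) // self.bin_size
            for b in range(b0, b1 + 1):
                bs = b * self.bin_size
                be = min(bs + self.bin_size, length)
                ov = min(be, e_in) - max(bs, s_in)
                total += self.values[off + b] * ov
        return total / (end - start)
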