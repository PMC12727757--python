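"""Plain-text I/O: chrom.sizes, BED, GTF gene records, bedGraph, TSV tables.

Writers emit floats in shortest exact (round-trip) decimal form so that
write -> read reproduces the in-memory object bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinnedTrack, GenomeLayout, GenomicsError, IntervalSet
from .tables import ExpressionDelta, GeneTable, MSCalibration


def _fmt(v: float) -> str:
    return repr(float(v))


# -- chrom.sizes ---------------------------------------------------------
def read_chrom_sizes(path) -> GenomeLayout:
    names, lengths = [], []
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise GenomicsError(f"{path}:{i}: expected two tab-separated columns")
        names.append(parts[0])
        lengths.append(int(parts[1]))
    return GenomeLayout(tuple(names), tuple(lengths))


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{l}\n" for c, l in layout.lengths.items())
    )


# -- BED / GTF -----------------------------------------------------------
def read_intervals(path, format: str = "bed", layout: GenomeLayout | None = None) -> IntervalSet:
    """Read BED3/6 or GTF (gene records only) into an IntervalSet.

    GTF 1-based closed coordinates are shifted to 0-based half-open.
    """
    if format not in ("bed", "gtf"):
        raise GenomicsError(f"unsupported format: {format!r}")
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        try:
            if format == "bed":
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else "."
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
                strand = parts[5] if len(parts) > 5 else "."
            else:
                if len(parts) < 9:
                    raise ValueError("fewer than 9 GTF fields")
                if parts[2] != "gene":
                    continue
                chrom = parts[0]
                start, end = int(parts[3]) - 1, int(parts[4])
                strand = parts[6] if parts[6] in ("+", "-") else "."
                m = re.search(r'gene_id "([^"]+)"', parts[8])
                name = m.group(1) if m else "."
                score = 0.0
            if start >= end:
                raise ValueError(f"start >= end ({start} >= {end})")
        except (ValueError, IndexError) as exc:
            raise GenomicsError(f"{path}:{i}: malformed {format} line: {exc}") from None
        rows.append((chrom, start, end, name, score, strand))
    iset = IntervalSet.from_records(rows)
    if layout is not None:
        iset.check_in_layout(layout)
    return iset


def write_bed(iset: IntervalSet, path, columns: int = 6) -> None:
    with open(path, "w") as fh:
        for _, r in iset.df.iterrows():
            fields = [r["chrom"], str(r["start"]), str(r["end"])]
            if columns >= 4:
                fields.append(str(r["name"]))
            if columns >= 5:
                fields.append(_fmt(r["score"]))
            if columns >= 6:
                fields.append(str(r["strand"]))
            fh.write("\t".join(fields) + "\n")


# -- bedGraph ------------------------------------------------------------
def write_bedgraph(track: BinnedTrack, path) -> None:
    """One line per bin; zero bins included so the grid is explicit."""
    bins = track.bin_intervals().df
    with open(path, "w") as fh:
        fh.write(f"# units={track.units} bin_size={track.bin_size}\n")
        for (_, r), v in zip(bins.iterrows(), track.values):
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{_fmt(v)}\n")


def read_bedgraph(path, layout: GenomeLayout, bin_size: int, units: str | None = None) -> BinnedTrack:
    values = np.zeros(layout.total_bins(bin_size), dtype=np.float64)
    offsets = layout.bin_offsets(bin_size)
    lengths = layout.lengths
    header_units = None
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith("#"):
            m = re.search(r"units=(\w+)", line)
            if m:
                header_units = m.group(1)
            continue
        if not line.strip() or line.startswith(("track", "browser")):
            continue
        parts = line.split("\t")
        try:
            chrom, start, end, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        except (ValueError, IndexError) as exc:
            raise GenomicsError(f"{path}:{i}: malformed bedGraph line: {exc}") from None
        if chrom not in offsets:
            raise GenomicsError(f"{path}:{i}: unknown chromosome {chrom!r}")
        if end > lengths[chrom]:
            raise GenomicsError(f"{path}:{i}: interval exceeds chromosome end")
        if start % bin_size or (end - start) > bin_size:
            raise GenomicsError(
                f"{path}:{i}: record not aligned to {bin_size}-bp grid"
            )
        values[offsets[chrom] + start // bin_size] = val
    return BinnedTrack(layout, bin_size, values, units or header_units or "count")


# -- TSV tables ----------------------------------------------------------
def write_gene_table(genes: GeneTable, path) -> None:
    genes.df.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> GeneTable:
    return GeneTable(pd.read_csv(path, sep="\t"))


def write_ms_calibration(cal: MSCalibration, path) -> None:
    cal.to_frame().to_csv(path, sep="\t", index=False)


def read_ms_calibration(path) -> MSCalibration:
    return MSCalibration.from_frame(pd.read_csv(path, sep="\t"))


def write_expression(delta: ExpressionDelta, path) -> None:
    delta.df.to_csv(path, sep="\t", index=False)


def read_expression(path) -> ExpressionDelta:
    return ExpressionDelta(pd.read_csv(path, sep="\t"))


# -- manifest ------------------------------------------------------------
def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(paths: dict[str, str | Path], out_path, extra: dict | None = None) -> dict:
    """Manifest of named output files with content hashes (no timestamps)."""
    manifest = {
        "files": {
            key: {"path": str(Path(p).name), "sha256": sha256_file(p)}
            for key, p in sorted(paths.items())
        }
    }
    if extra:
        manifest.update(extra)
    Path(out_path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
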