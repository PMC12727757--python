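"""Chromatin-loop span classes, lost-loop identification, and the
anchor -> enhancer -> nearest-gene expression procedure.

Loops are focal pairwise contacts between two genomic anchors called on a
fixed bin grid (25 kb here).  Long-range loops span more than 500 kb; the
lost-loop procedure finds long-range loops present in the parental condition
with no anchor-matched counterpart in the treated condition, then asks whether
genes nearest to enhancers inside the lost anchors are preferentially
down-regulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomicsError, IntervalSet
from .tables import ExpressionDelta, GeneTable

_LOOP_COLS = ["chrom", "start1", "end1", "start2", "end2", "score"]


class LoopSet:
    """Anchor-pair records on a fixed calling grid (same chrom per record)."""

    def __init__(self, df: pd.DataFrame, bin_size: int):
        df = df.copy()
        for col in ("chrom", "start1", "end1", "start2", "end2"):
            if col not in df.columns:
                raise GenomicsError(f"LoopSet missing column {col!r}")
        if "score" not in df.columns:
            df["score"] = 0.0
        for col in ("start1", "end1", "start2", "end2"):
            df[col] = df[col].astype(np.int64)
        if ((df["start1"] >= df["end1"]) | (df["start2"] >= df["end2"])).any():
            raise GenomicsError("anchor intervals must have start < end")
        if (df["start1"] >= df["start2"]).any():
            raise GenomicsError("anchor1 must precede anchor2")
        if (df["end1"] > df["start2"]).any():
            raise GenomicsError("anchors must not overlap")
        self.df = (
            df[_LOOP_COLS]
            .sort_values(["chrom", "start1", "start2"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.bin_size = int(bin_size)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def spans(self) -> np.ndarray:
        """Anchor midpoint-to-midpoint distances (bp)."""
        mid1 = (self.df["start1"] + self.df["end1"]) / 2.0
        mid2 = (self.df["start2"] + self.df["end2"]) / 2.0
        return (mid2 - mid1).values

    def anchors(self) -> IntervalSet:
        """All anchor intervals (each loop contributes two records)."""
        a = self.df[["chrom", "start1", "end1"]].rename(
            columns={"start1": "start", "end1": "end"}
        )
        b = self.df[["chrom", "start2", "end2"]].rename(
            columns={"start2": "start", "end2": "end"}
        )
        return IntervalSet(pd.concat([a, b], ignore_index=True))

    def subset(self, mask: np.ndarray) -> "LoopSet":
        return LoopSet(self.df[np.asarray(mask)].reset_index(drop=True), self.bin_size)


def classify_loop_spans(loops: LoopSet, cutoff: int = 500_000) -> tuple[LoopSet, LoopSet]:
    """Partition into (long, short): long iff span strictly exceeds cutoff."""
    long_mask = loops.spans > cutoff
    return loops.subset(long_mask), loops.subset(~long_mask)


def find_lost_loops(
    parental: LoopSet,
    treated: LoopSet,
    span_cutoff: int = 500_000,
    tolerance_bins: int = 0,
) -> LoopSet:
    """Long-range parental loops with no anchor-matched treated loop.

    Both sets are first restricted to spans > ``span_cutoff``.  A parental
    loop is lost iff no treated loop on the same chromosome has both anchor
    start bins within ``tolerance_bins`` grid bins of the parental anchors.
    """
    if parental.bin_size != treated.bin_size:
        raise GenomicsError("loop sets must share the calling grid")
    w = parental.bin_size
    par_long, _ = classify_loop_spans(parental, span_cutoff)
    tre_long, _ = classify_loop_spans(treated, span_cutoff)
    tol = tolerance_bins * w
    lost = []
    tre_by_chrom = dict(tuple(tre_long.df.groupby("chrom", sort=False)))
    for idx, r in par_long.df.iterrows():
        t = tre_by_chrom.get(r["chrom"])
        if t is None:
            lost.append(idx)
            continue
        match = (
            (np.abs(t["start1"] - r["start1"]) <= tol)
            & (np.abs(t["start2"] - r["start2"]) <= tol)
        )
        if not match.any():
            lost.append(idx)
    return LoopSet(par_long.df.loc[lost].reset_index(drop=True), w)


def nearest_gene(
    chrom: str, start: int, end: int, genes: GeneTable, distance_to: str = "body"
) -> str | None:
    """Id of the protein-coding gene nearest to [start, end) on ``chrom``.

    Distance to the gene body (0 if overlapping) by default, or to the TSS
    with ``distance_to='tss'``.  Ties go to the gene with the smaller start.
    """
    sub = genes.protein_coding().df
    sub = sub[sub["chrom"] == chrom]
    if sub.empty:
        return None
    if distance_to == "body":
        # 0 when overlapping; gap+1 otherwise so adjacency != overlap
        dist = np.maximum(
            np.where((sub["start"] < end) & (sub["end"] > start), 0,
                     np.maximum(sub["start"] - end, start - sub["end"]) + 1),
            0,
        )
    elif distance_to == "tss":
        tss = np.where(sub["strand"] == "-", sub["end"] - 1, sub["start"])
        dist = np.where(
            (tss >= start) & (tss < end), 0, np.minimum(np.abs(tss - start), np.abs(tss - (end - 1)))
        )
    else:
        raise GenomicsError(f"unknown distance_to: {distance_to!r}")
    sub = sub.assign(_d=dist).sort_values(["_d", "start", "gene_id"], kind="mergesort")
    return str(sub.iloc[0]["gene_id"])


def loop_anchor_enhancer_genes(
    lost: LoopSet,
    enhancers: IntervalSet,
    genes: GeneTable,
    deltas: ExpressionDelta,
    distance_to: str = "body",
) -> tuple[pd.DataFrame, dict]:
    """Genes nearest to enhancers inside lost-loop anchors, with shift counts.

    Enhancers overlapping either anchor by >=1 bp are collected; each is
    mapped to its nearest protein-coding gene; genes are deduplicated; the
    log2FC distribution is summarized by sign counts and compared with the
    complement gene set by a two-sided rank-sum test.
    """
    anchors = lost.anchors()
    hit = enhancers.overlap_filter(anchors)
    gene_ids: list[str] = []
    rows = []
    for _, e in hit.df.iterrows():
        gid = nearest_gene(e["chrom"], e["start"], e["end"], genes, distance_to)
        if gid is None:
            continue
        rows.append(
            {"enhancer": e["name"], "chrom": e["chrom"], "start": e["start"],
             "end": e["end"], "gene_id": gid}
        )
        gene_ids.append(gid)
    assoc = pd.DataFrame(rows, columns=["enhancer", "chrom", "start", "end", "gene_id"])
    unique_ids = list(dict.fromkeys(gene_ids))
    expr = deltas.lookup(unique_ids)
    missing = set(unique_ids) - set(expr["gene_id"])
    if missing:
        import warnings

        warnings.warn(f"{len(missing)} associated gene(s) lack expression records")
    lfc = expr["log2fc"].values
    summary: dict = {
        "n_genes": int(len(expr)),
        "n_up": int((lfc > 0).sum()),
        "n_down": int((lfc < 0).sum()),
        "n_zero": int((lfc == 0).sum()),
    }
    rest = deltas.df[~deltas.df["gene_id"].isin(set(expr["gene_id"]))]["log2fc"].values
    if len(lfc) and len(rest):
        stat, p = stats.ranksums(lfc, rest)
        summary["ranksum_stat"], summary["ranksum_p"] = float(stat), float(p)
    assoc = assoc[assoc["gene_id"].isin(set(expr["gene_id"]))].reset_index(drop=True)
    return assoc, summary


# -- BEDPE I/O -----------------------------------------------------------
def write_bedpe(loops: LoopSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_size={loops.bin_size}\n")
        for _, r in loops.df.iterrows():
            fh.write(
                f"{r['chrom']}\t{r['start1']}\t{r['end1']}\t"
                f"{r['chrom']}\t{r['start2']}\t{r['end2']}\t"
                f".\t{repr(float(r['score']))}\n"
            )


def read_bedpe(path, bin_size: int | None = None) -> LoopSet:
    import re

    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith("#"):
            m = re.search(r"bin_size=(\d+)", line)
            if m:
                bin_size = bin_size or int(m.group(1))
            continue
        if not line.strip():
            continue
        p = line.split("\t")
        try:
            if p[0] != p[3]:
                raise ValueError("trans loop (different chromosomes)")
            rows.append(
                {"chrom": p[0], "start1": int(p[1]), "end1": int(p[2]),
                 "start2": int(p[4]), "end2": int(p[5]),
                 "score": float(p[7]) if len(p) > 7 and p[7] != "." else 0.0}
            )
        except (ValueError, IndexError) as exc:
            raise GenomicsError(f"{path}:{i}: malformed BEDPE line: {exc}") from None
    if bin_size is None:
        raise GenomicsError("bin_size required (header or argument)")
    return LoopSet(pd.DataFrame(rows, columns=_LOOP_COLS), bin_size)
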