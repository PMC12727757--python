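"""Tabular domain types: gene tables, MS calibrations, expression deltas."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicsError, IntervalSet

_GENE_COLS = ["gene_id", "chrom", "start", "end", "strand", "baseline_fpkm",
              "raw_counts", "biotype"]


class GeneTable:
    """Per-gene annotation with baseline expression.

    Columns: gene_id, chrom, start, end, strand, baseline_fpkm, raw_counts,
    biotype.  Gene length is end - start (bp).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in _GENE_COLS if c not in df.columns]
        if missing:
            raise GenomicsError(f"GeneTable missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            raise GenomicsError("gene ids must be unique")
        if (df["baseline_fpkm"] < 0).any():
            raise GenomicsError("baseline_fpkm must be >= 0")
        if (df["start"] >= df["end"]).any():
            raise GenomicsError("gene start must be < end")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self.df = df[_GENE_COLS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).values

    def intervals(self, names: bool = True) -> IntervalSet:
        df = self.df.rename(columns={"gene_id": "name"})
        df["score"] = 0.0
        return IntervalSet(df[["chrom", "start", "end", "name", "score", "strand"]])

    def subset(self, gene_ids) -> "GeneTable":
        ids = set(gene_ids)
        return GeneTable(self.df[self.df["gene_id"].isin(ids)].reset_index(drop=True))

    def protein_coding(self) -> "GeneTable":
        return GeneTable(
            self.df[self.df["biotype"] == "protein_coding"].reset_index(drop=True)
        )

    def tss(self) -> pd.DataFrame:
        """Strand-aware transcription start sites (0-based position)."""
        pos = np.where(self.df["strand"] == "-", self.df["end"] - 1, self.df["start"])
        return pd.DataFrame(
            {"gene_id": self.df["gene_id"], "chrom": self.df["chrom"], "tss": pos}
        )


class MSCalibration:
    """Genome-wide modification percentages from mass spectrometry.

    Maps (mark, condition) -> percent of histones carrying the mark (0-100),
    averaged over replicates.
    """

    def __init__(self, table: dict[tuple[str, str], float]):
        for key, pct in table.items():
            if not 0.0 <= pct <= 100.0:
                raise GenomicsError(f"MS percentage out of [0,100] for {key}: {pct}")
        self.table = dict(table)

    def pct(self, mark: str, condition: str) -> float:
        try:
            return self.table[(mark, condition)]
        except KeyError:
            raise GenomicsError(f"no MS entry for ({mark!r}, {condition!r})") from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mark": m, "condition": c, "percent": p}
            for (m, c), p in sorted(self.table.items())
        ]
        return pd.DataFrame(rows, columns=["mark", "condition", "percent"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MSCalibration":
        return cls(
            {
                (r["mark"], r["condition"]): float(r["percent"])
                for _, r in df.iterrows()
            }
        )


class ExpressionDelta:
    """Per-gene expression response: log2FC, adjusted p-value, baseline FPKM."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in ("gene_id", "log2fc", "padj", "baseline_fpkm"):
            if col not in df.columns:
                raise GenomicsError(f"ExpressionDelta missing column {col!r}")
        ok = df["padj"].isna() | ((df["padj"] >= 0) & (df["padj"] <= 1))
        if not ok.all():
            raise GenomicsError("padj must lie in [0,1] or be missing")
        self.df = df[["gene_id", "log2fc", "padj", "baseline_fpkm"]].reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    def lookup(self, gene_ids) -> pd.DataFrame:
        """Rows for the requested genes, in request order; missing genes dropped."""
        idx = self.df.set_index("gene_id")
        present = [g for g in gene_ids if g in idx.index]
        return idx.loc[present].reset_index()
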