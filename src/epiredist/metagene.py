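"""Gene stratification and scaled metagene (scale-regions) matrices.

Genes are filtered to the interquartile length band (computed from the input,
not hard-coded), cleaned of neighbours within 2 kb of the TSS/TES, and
stratified into silent / lowly expressed / highly expressed groups.  For each
group, signal over a fixed upstream flank, a length-rescaled gene body and a
fixed downstream flank is averaged into a genes x columns matrix; gene bodies
are rescaled by coverage-weighted averaging so the body mean is conserved, and
minus-strand genes are column-reversed so column 0 is always the 5' end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinnedTrack, GenomicsError
from .tables import GeneTable


@dataclass(frozen=True)
class MetageneParams:
    upstream: int = 2000
    downstream: int = 2000
    body: int = 20000
    bin: int = 500

    def __post_init__(self) -> None:
        for name in ("upstream", "downstream", "body"):
            if getattr(self, name) % self.bin:
                raise GenomicsError(f"{name} must be a multiple of bin")

    @property
    def n_columns(self) -> int:
        return (self.upstream + self.body + self.downstream) // self.bin


@dataclass(frozen=True)
class GeneGroups:
    silent: tuple[str, ...]
    low: tuple[str, ...]
    high: tuple[str, ...]
    n: int


def select_gene_groups(
    genes: GeneTable,
    n: int = 2000,
    seed: int = 0,
    fpkm_floor: float = 0.1,
    flank_bp: int = 2000,
) -> GeneGroups:
    """Filter and stratify protein-coding genes into expression groups.

    1. keep genes with length within [Q25, Q75] of the input length
       distribution (linear-interpolation percentiles);
    2. drop genes whose [TSS - flank, TES + flank] window overlaps another
       gene body;
    3. silent = ``n`` genes sampled (seeded) from the zero-count pool;
    4. among genes at or above ``fpkm_floor``: bottom ``n`` by FPKM = low,
       top ``n`` = high.

    Pools smaller than ``n`` are used whole, with a warning.
    """
    pc = genes.protein_coding()
    if len(pc) == 0:
        raise GenomicsError("no protein-coding genes")
    lengths = pc.lengths
    q25, q75 = np.percentile(lengths, [25, 75])
    band = pc.df[(lengths >= q25) & (lengths <= q75)].copy()

    # neighbour filter: expanded window vs every other gene body
    all_df = pc.df
    keep = []
    for _, g in band.iterrows():
        w0, w1 = g["start"] - flank_bp, g["end"] + flank_bp
        others = all_df[
            (all_df["chrom"] == g["chrom"]) & (all_df["gene_id"] != g["gene_id"])
        ]
        if not ((others["start"] < w1) & (others["end"] > w0)).any():
            keep.append(g["gene_id"])
    band = band[band["gene_id"].isin(keep)]

    def take(pool: pd.DataFrame, how: str) -> tuple[str, ...]:
        if len(pool) < n:
            warnings.warn(
                f"{how} pool has {len(pool)} genes (< requested {n}); using all"
            )
        if how == "silent":
            rng = np.random.default_rng(seed)
            ids = np.sort(pool["gene_id"].values)
            k = min(n, len(ids))
            return tuple(sorted(rng.choice(ids, size=k, replace=False)))
        ordered = pool.sort_values(["baseline_fpkm", "gene_id"], kind="mergesort")
        if how == "low":
            return tuple(ordered["gene_id"].head(min(n, len(ordered))))
        return tuple(ordered["gene_id"].tail(min(n, len(ordered))))

    silent_pool = band[band["raw_counts"] == 0]
    expr_pool = band[band["baseline_fpkm"] >= fpkm_floor]
    silent = take(silent_pool, "silent")
    low = take(expr_pool, "low")
    high = take(expr_pool, "high")
    return GeneGroups(silent=silent, low=low, high=high, n=n)


def _integrate(track: BinnedTrack, chrom: str, x0: float, x1: float) -> float:
    """Integral of the per-bp step signal over [x0, x1); out-of-range bp -> 0."""
    length = track.layout.lengths[chrom]
    off = track.layout.bin_offsets(track.bin_size)[chrom]
    a, b = max(x0, 0.0), min(x1, float(length))
    if b <= a:
        return 0.0
    w = track.bin_size
    b0, b1 = int(a // w), int(math.ceil(b / w)) - 1
    total = 0.0
    for bi in range(b0, b1 + 1):
        bs, be = bi * w, min((bi + 1) * w, length)
        ov = min(be, b) - max(bs, a)
        if ov > 0:
            total += track.values[off + bi] * ov
    return total


def compute_metagene_matrix(
    track: BinnedTrack,
    genes: GeneTable,
    group: tuple[str, ...] | list[str],
    params: MetageneParams = MetageneParams(),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Scaled-region signal matrix for one gene group, plus column means.

    Flank columns sample fixed windows at bin resolution; body columns are
    equal-length segments of the gene body (coverage-weighted means, which
    conserves the body mean for any gene length).  Minus-strand rows are
    reversed so column 0 is the 5' end.  Positions outside the chromosome
    contribute 0 (missing data as zero); all-zero rows are dropped.
    """
    ids = list(group)
    if not ids:
        raise GenomicsError("empty gene group")
    sub = genes.subset(ids)
    n_up = params.upstream // params.bin
    n_body = params.body // params.bin
    n_down = params.downstream // params.bin
    rows, kept = [], []
    for _, g in sub.df.iterrows():
        chrom, s, e = g["chrom"], float(g["start"]), float(g["end"])
        cols = np.empty(params.n_columns)
        # genomic left-to-right: upstream flank, body segments, downstream flank
        for i in range(n_up):
            a = s - params.upstream + i * params.bin
            cols[i] = _integrate(track, chrom, a, a + params.bin) / params.bin
        seg = (e - s) / n_body
        for i in range(n_body):
            a = s + i * seg
            cols[n_up + i] = _integrate(track, chrom, a, a + seg) / seg
        for i in range(n_down):
            a = e + i * params.bin
            cols[n_up + n_body + i] = (
                _integrate(track, chrom, a, a + params.bin) / params.bin
            )
        if g["strand"] == "-":
            cols = cols[::-1]
        if np.any(cols != 0.0):
            rows.append(cols)
            kept.append(g["gene_id"])
    if not rows:
        raise GenomicsError("all rows are zero after missing-data substitution")
    matrix = pd.DataFrame(rows, index=kept)
    return matrix, matrix.values.mean(axis=0)


def write_metagene_matrix(matrix: pd.DataFrame, params: MetageneParams, path) -> None:
    """TSV with a JSON header line recording parameters and row count."""
    import json

    header = json.dumps(
        {"upstream": params.upstream, "downstream": params.downstream,
         "body": params.body, "bin": params.bin, "n_rows": len(matrix)},
        sort_keys=True,
    )
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        matrix.to_csv(fh, sep="\t", header=False)
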