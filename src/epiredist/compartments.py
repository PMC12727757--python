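"""Compartment scores, saddle strength and contact-range statistics.

Works on per-chromosome symmetric binned contact matrices (cis only).  The
observed/expected (O/E) transform divides each diagonal by its mean over
unmasked cells; the compartment score is the leading eigenvector of the
Pearson correlation matrix of the O/E map, sign-phased against a reference
track (e.g. GC content or a mark density) so that positive scores mean the
active A compartment.  Saddle strength summarizes checkerboarding: mean O/E
among the extreme same-compartment bin pairs over the extreme cross-compartment
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomicsError


@dataclass
class ContactMatrix:
    """Symmetric binned cis contact map for one chromosome."""

    chrom: str
    bin_size: int
    matrix: np.ndarray
    bad_bins: np.ndarray | None = None  # boolean mask of excluded bins

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise GenomicsError("contact matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise GenomicsError("contact matrix must be symmetric")
        if self.bad_bins is None:
            self.bad_bins = np.zeros(self.matrix.shape[0], dtype=bool)
        else:
            self.bad_bins = np.asarray(self.bad_bins, dtype=bool)
            if self.bad_bins.shape != (self.matrix.shape[0],):
                raise GenomicsError("bad_bins length mismatch")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CompartmentTrack:
    """Per-bin compartment eigenvector scores (NaN for masked bins)."""

    chrom: str
    bin_size: int
    scores: np.ndarray


@dataclass
class SaddleResult:
    strength_aa: float
    strength_bb: float
    q: float
    grid: pd.DataFrame | None = None


def oe_transform(m: ContactMatrix) -> ContactMatrix:
    """Observed/expected: divide each diagonal by its mean over unmasked cells."""
    good = ~m.bad_bins
    if not good.any():
        raise GenomicsError("all bins masked")
    n = m.n
    out = np.full((n, n), np.nan)
    gi = np.flatnonzero(good)
    for d in range(n):
        i = np.arange(0, n - d)
        j = i + d
        keep = good[i] & good[j]
        if not keep.any():
            continue
        exp = m.matrix[i[keep], j[keep]].mean()
        if exp > 0:
            out[i[keep], j[keep]] = m.matrix[i[keep], j[keep]] / exp
            out[j[keep], i[keep]] = out[i[keep], j[keep]]
    return ContactMatrix(m.chrom, m.bin_size, np.nan_to_num(out, nan=0.0), m.bad_bins)


def compartment_score(m: ContactMatrix, phasing: np.ndarray) -> CompartmentTrack:
    """Leading eigenvector of the correlation matrix of O/E, sign-phased.

    The sign is flipped, if needed, so the Pearson correlation of the scores
    with the ``phasing`` track is non-negative.  Masked bins get NaN.
    """
    phasing = np.asarray(phasing, dtype=np.float64)
    if phasing.shape != (m.n,):
        raise GenomicsError("phasing track length mismatch")
    oe = oe_transform(m)
    good = np.flatnonzero(~m.bad_bins)
    if len(good) < 3:
        raise GenomicsError("need at least 3 unmasked bins")
    sub = oe.matrix[np.ix_(good, good)]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    if not np.all(np.isfinite(corr)):
        raise GenomicsError("degenerate correlation matrix (constant rows)")
    vals, vecs = np.linalg.eigh(corr)
    vec = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    ph = phasing[good]
    if np.std(ph) > 0 and np.std(vec) > 0:
        r = np.corrcoef(vec, ph)[0, 1]
        if r < 0:
            vec = -vec
    scores = np.full(m.n, np.nan)
    scores[good] = vec
    return CompartmentTrack(m.chrom, m.bin_size, scores)


def saddle_strength(
    oe: ContactMatrix,
    scores: CompartmentTrack,
    q: float = 0.20,
    ab_mode: str = "saddle-corner",
) -> SaddleResult:
    """Compartment-interaction strength from an O/E map and scores.

    Bins are ranked by score.  AA = mean O/E over off-diagonal cell pairs with
    both bins in the top ``q`` fraction; BB = both in the bottom ``q``.  The
    cross-compartment denominator is either the saddle corner (one bin in the
    top ``q``, one in the bottom ``q``; default) or, with
    ``ab_mode='global-bottom'``, the mean of the lowest ``q`` fraction of all
    cross-sign cell values.
    """
    if not 0 < q <= 0.5:
        raise GenomicsError("q must lie in (0, 0.5]")
    if ab_mode not in ("saddle-corner", "global-bottom"):
        raise GenomicsError(f"unknown ab_mode: {ab_mode!r}")
    good = np.flatnonzero(~oe.bad_bins & np.isfinite(scores.scores))
    if len(good) < 4:
        raise GenomicsError("too few scored bins for saddle statistics")
    s = scores.scores[good]
    order = np.argsort(s, kind="stable")
    k = max(1, int(np.floor(q * len(good))))
    bottom = good[order[:k]]
    top = good[order[-k:]]

    def cell_mean(rows, cols):
        sub = oe.matrix[np.ix_(rows, cols)]
        ii, jj = np.meshgrid(rows, cols, indexing="ij")
        vals = sub[ii != jj] if np.intersect1d(rows, cols).size else sub.ravel()
        return float(vals.mean()) if vals.size else np.nan

    aa = cell_mean(top, top)
    bb = cell_mean(bottom, bottom)
    if ab_mode == "saddle-corner":
        ab = cell_mean(top, bottom)
    else:
        pos = good[s > 0] if np.any(s > 0) else top
        neg = good[s < 0] if np.any(s < 0) else bottom
        vals = np.sort(oe.matrix[np.ix_(pos, neg)].ravel(), kind="stable")
        kk = max(1, int(np.floor(q * len(vals))))
        ab = float(vals[:kk].mean())
    if not ab or not np.isfinite(ab):
        raise GenomicsError("cross-compartment denominator is zero or undefined")
    return SaddleResult(strength_aa=aa / ab, strength_bb=bb / ab, q=q)


def cis_range_fractions(
    m: ContactMatrix | pd.DataFrame,
    long_cutoff: int = 10_000_000,
    short_lo: int = 1_000,
) -> tuple[float, float]:
    """Fractions of cis contact signal at long (> cutoff) vs short range.

    Sub-``short_lo`` separations (self/adjacent ligation artifacts) are
    excluded from the denominator.  Accepts a ContactMatrix or a DataFrame
    with columns ``separation`` and ``count``.
    """
    if isinstance(m, ContactMatrix):
        i, j = np.triu_indices(m.n)
        good = ~(m.bad_bins[i] | m.bad_bins[j])
        sep = (j - i)[good] * m.bin_size
        weight = m.matrix[i, j][good]
    else:
        sep = m["separation"].values.astype(float)
        weight = m["count"].values.astype(float)
    considered = sep >= short_lo
    total = float(weight[considered].sum())
    if total <= 0:
        raise GenomicsError("no cis contacts at or above the minimum separation")
    frac_long = float(weight[considered & (sep > long_cutoff)].sum()) / total
    frac_short = float(
        weight[considered & (sep <= long_cutoff)].sum()
    ) / total
    return frac_long, frac_short


def compartment_shift_counts(
    scores_parental: np.ndarray, scores_treated: np.ndarray
) -> dict[str, int]:
    """Counts of per-bin compartment identity changes (positive score = A)."""
    a = np.asarray(scores_parental, dtype=float)
    b = np.asarray(scores_treated, dtype=float)
    if a.shape != b.shape:
        raise GenomicsError("score vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]

    def lab(v):
        return np.where(v > 0, "A", np.where(v < 0, "B", "0"))

    la, lb = lab(a), lab(b)
    counts = {"A->A": 0, "A->B": 0, "B->A": 0, "B->B": 0, "zero": 0}
    for x, y in zip(la, lb):
        if x == "0" or y == "0":
            counts["zero"] += 1
        else:
            counts[f"{x}->{y}"] += 1
    return counts


# -- matrix I/O (dense TSV and COO triplets) -----------------------------
def write_dense_matrix(m: ContactMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# chrom={m.chrom} bin_size={m.bin_size}\n")
        for row in m.matrix:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_dense_matrix(path, chrom: str | None = None, bin_size: int | None = None) -> ContactMatrix:
    lines = Path(path).read_text().splitlines()
    rows = []
    for line in lines:
        if line.startswith("#"):
            import re

            mm = re.search(r"chrom=(\S+) bin_size=(\d+)", line)
            if mm:
                chrom = chrom or mm.group(1)
                bin_size = bin_size or int(mm.group(2))
            continue
        if line.strip():
            rows.append([float(v) for v in line.split("\t")])
    if chrom is None or bin_size is None:
        raise GenomicsError("chrom and bin_size required (header or arguments)")
    return ContactMatrix(chrom, bin_size, np.array(rows))


def write_coo_matrix(m: ContactMatrix, path) -> None:
    """Upper-triangle nonzero triplets: bin1, bin2, count."""
    i, j = np.triu_indices(m.n)
    vals = m.matrix[i, j]
    nz = vals != 0
    with open(path, "w") as fh:
        fh.write(f"# chrom={m.chrom} bin_size={m.bin_size} n_bins={m.n}\n")
        for a, b, v in zip(i[nz], j[nz], vals[nz]):
            fh.write(f"{a}\t{b}\t{repr(float(v))}\n")


def read_coo_matrix(path) -> ContactMatrix:
    import re

    chrom = bin_size = n = None
    triplets = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            mm = re.search(r"chrom=(\S+) bin_size=(\d+) n_bins=(\d+)", line)
            if mm:
                chrom, bin_size, n = mm.group(1), int(mm.group(2)), int(mm.group(3))
            continue
        if line.strip():
            a, b, v = line.split("\t")
            triplets.append((int(a), int(b), float(v)))
    if n is None:
        raise GenomicsError("COO matrix file missing header")
    mat = np.zeros((n, n))
    for a, b, v in triplets:
        mat[a, b] = v
        mat[b, a] = v
    return ContactMatrix(chrom, bin_size, mat)
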