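"""Synthetic epigenome generator with known planted truth.

Emulates the study conditions of a heterochromatin-redistribution experiment
at desk scale: a small genome carrying megabase-scale, gene-poor
heterochromatin domains marked in the parental condition; a treated condition
in which domain signal collapses to background while the mark invades gene
bodies in proportion to expression; an input control; mass-spectrometry global
percentages consistent with the simulated tracks; checkerboard contact maps
with distance decay and planted loops whose long-range subset is dropped in
the treated condition; and expression responses coupled to the planted domain
loss (de-repression) and to the dropped loops (enhancer-target
down-regulation).

Default parameters define the fixed study conditions: 2 chromosomes x 20 Mb,
5 genes/Mb, a quarter of the genome in 2-Mb domains with 8-fold parental
enrichment, negative-binomial counts (dispersion 0.1) at 2e6 tags per
condition, base modification frequency 5% per unenriched bin, +2 log2FC
(sd 0.5) for genes in lost domains and -1.5 for dropped-loop target genes,
Hi-C compartment contrast 1.0 (parental) vs 0.3 (treated) with decay exponent
1.0 and loop strength 2.0.

One master seed fans out to per-component child seeds through
``numpy.random.SeedSequence([master_seed, component_index])`` with fixed
component indices (genome=0, tracks=1, contacts=2, expression=3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .compartments import ContactMatrix
from .genome import BinnedTrack, GenomeLayout, GenomicsError, IntervalSet
from .loops import LoopSet, nearest_gene
from .tables import ExpressionDelta, GeneTable, MSCalibration

_COMPONENT_INDEX = {"genome": 0, "tracks": 1, "contacts": 2, "expression": 3}


def child_seed(master_seed: int, component: str) -> np.random.SeedSequence:
    """Deterministic per-component seed derived from the master seed."""
    return np.random.SeedSequence([int(master_seed), _COMPONENT_INDEX[component]])


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    master_seed: int
    domains: IntervalSet
    domain_folds: np.ndarray  # parental enrichment fold per domain
    genic_gain_coef: float
    true_pct: dict[str, float] = field(default_factory=dict)  # condition -> %
    loops: pd.DataFrame | None = None  # chrom,start1,end1,start2,end2,dropped
    loop_bin_size: int = 25_000
    loop_target_genes: tuple[str, ...] = ()
    expression_class: dict[str, str] = field(default_factory=dict)
    layout: GenomeLayout | None = None
    genes: GeneTable | None = None
    enhancers: IntervalSet | None = None


# ----------------------------------------------------------------------
def make_genome_annotation(
    n_chrom: int = 2,
    chrom_length_bp: int = 20_000_000,
    gene_density: float = 5.0,
    domain_fraction: float = 0.25,
    seed: int = 0,
    *,
    domain_size_bp: int = 2_000_000,
    domain_min_gap_bp: int = 3_000_000,
    domain_grid_bp: int = 100_000,
    gene_length_median_bp: float = 20_000.0,
    gene_length_sigma: float = 0.6,
    gene_min_spacing_bp: int = 4_000,
    domain_gene_bias: float = 0.6,
    domain_fold: float = 8.0,
    genic_gain_coef: float = 0.5,
    silent_fraction_in_domain: float = 0.7,
    silent_fraction_outside: float = 0.25,
    enhancers_per_mb: float = 2.0,
    enhancer_size_bp: int = 1_000,
    loops_per_chrom: int = 12,
    loop_bin_size: int = 25_000,
    loop_drop_fraction: float = 0.7,
    max_place_retries: int = 200,
) -> tuple[GenomeLayout, GeneTable, IntervalSet, SyntheticTruth]:
    """Build a small genome with planted domains, genes, enhancers and loops.

    Domains are placed on a 100-kb grid with a minimum inter-domain gap so
    that downstream 1-Mb merging cannot fuse neighbouring planted domains.
    Genes are drawn with log-normal lengths and placed with strongly reduced
    probability inside domains (``domain_gene_bias``); enhancers are placed in
    intergenic, non-domain space, plus one at each planted loop anchor.
    """
    if not 0 <= domain_fraction < 1:
        raise GenomicsError("domain_fraction must lie in [0, 1)")
    rng = np.random.default_rng(child_seed(seed, "genome"))
    layout = GenomeLayout(
        tuple(f"chr{i + 1}" for i in range(n_chrom)),
        tuple(int(chrom_length_bp) for _ in range(n_chrom)),
    )
    total_bp = layout.total_bp

    # -- domains: round-robin per chromosome, jittered sorted placement ----
    n_domains = int(round(total_bp * domain_fraction / domain_size_bp))
    per_chrom = [n_domains // n_chrom + (1 if i < n_domains % n_chrom else 0)
                 for i in range(n_chrom)]
    edge = 5 * domain_grid_bp
    dom_rows = []
    for chrom, k in zip(layout.chrom_names, per_chrom):
        if k == 0:
            continue
        L = layout.lengths[chrom]
        slack = L - 2 * edge - k * domain_size_bp - (k - 1) * domain_min_gap_bp
        if slack < 0:
            raise GenomicsError("cannot place domains: chromosome too short")
        u = np.sort(rng.uniform(0, slack, size=k))
        for i in range(k):
            start = edge + u[i] + i * (domain_size_bp + domain_min_gap_bp)
            start = int(round(start / domain_grid_bp)) * domain_grid_bp
            dom_rows.append((chrom, start, start + domain_size_bp, f"domain{len(dom_rows) + 1}"))
    domains = IntervalSet.from_records(dom_rows)
    domain_folds = np.full(len(dom_rows), domain_fold, dtype=float)

    # -- genes -------------------------------------------------------------
    n_genes = int(round(total_bp / 1e6 * gene_density))
    mu = math.log(gene_length_median_bp)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chrom_names}
    dom_by_chrom = {
        c: domains.df[domains.df["chrom"] == c][["start", "end"]].values
        for c in layout.chrom_names
    }
    chrom_probs = np.array(layout.chrom_lengths, dtype=float)
    chrom_probs /= chrom_probs.sum()
    gene_rows = []
    for g in range(n_genes):
        length = int(np.clip(rng.lognormal(mu, gene_length_sigma), 1_000, None))
        for attempt in range(max_place_retries):
            chrom = rng.choice(layout.chrom_names, p=chrom_probs)
            L = layout.lengths[chrom]
            if length + 2 * gene_min_spacing_bp >= L:
                continue
            start = int(rng.integers(gene_min_spacing_bp, L - length - gene_min_spacing_bp))
            end = start + length
            doms = dom_by_chrom[chrom]
            in_domain = bool(
                len(doms) and np.any((doms[:, 0] < end) & (doms[:, 1] > start))
            )
            if in_domain and rng.uniform() < domain_gene_bias:
                continue
            clash = any(
                s - gene_min_spacing_bp < end and e + gene_min_spacing_bp > start
                for s, e in placed[chrom]
            )
            if clash:
                continue
            placed[chrom].append((start, end))
            silent_p = (
                silent_fraction_in_domain if in_domain else silent_fraction_outside
            )
            silent = rng.uniform() < silent_p
            fpkm = 0.0 if silent else float(rng.lognormal(math.log(8.0), 1.0))
            counts = 0 if silent else int(rng.poisson(fpkm * length / 1e3))
            gene_rows.append(
                {"gene_id": f"gene{g + 1:04d}", "chrom": chrom, "start": start,
                 "end": end, "strand": "+" if rng.uniform() < 0.5 else "-",
                 "baseline_fpkm": fpkm, "raw_counts": counts,
                 "biotype": "protein_coding", "_in_domain": in_domain}
            )
            break
        else:
            raise GenomicsError(
                f"could not place gene {g + 1}/{n_genes} after "
                f"{max_place_retries} retries — density infeasible"
            )
    gene_cols = ["gene_id", "chrom", "start", "end", "strand", "baseline_fpkm",
                 "raw_counts", "biotype", "_in_domain"]
    gene_df = pd.DataFrame(gene_rows, columns=gene_cols)
    in_domain_flags = gene_df.pop("_in_domain")
    genes = GeneTable(gene_df)

    # -- planted loops (and their anchor enhancers) ------------------------
    loop_rows = []
    gene_iv = {c: np.array(placed[c]) for c in layout.chrom_names}
    for chrom in layout.chrom_names:
        L = layout.lengths[chrom]
        n_bins_loop = L // loop_bin_size
        doms = dom_by_chrom[chrom]
        made = 0
        attempts = 0
        while made < loops_per_chrom and attempts < loops_per_chrom * max_place_retries:
            attempts += 1
            span = int(
                np.exp(rng.uniform(math.log(200_000), math.log(6_000_000)))
            )
            span = max(2, span // loop_bin_size) * loop_bin_size
            b1 = int(rng.integers(0, n_bins_loop - span // loop_bin_size - 1))
            s1 = b1 * loop_bin_size
            s2 = s1 + span
            ok = True
            for s in (s1, s2):
                if len(doms) and np.any(
                    (doms[:, 0] < s + loop_bin_size) & (doms[:, 1] > s)
                ):
                    ok = False
            if not ok:
                continue
            loop_rows.append(
                {"chrom": chrom, "start1": s1, "end1": s1 + loop_bin_size,
                 "start2": s2, "end2": s2 + loop_bin_size}
            )
            made += 1
    loop_df = pd.DataFrame(
        loop_rows, columns=["chrom", "start1", "end1", "start2", "end2"]
    ).drop_duplicates(["chrom", "start1", "start2"]).reset_index(drop=True)
    spans = loop_df["start2"] - loop_df["start1"]
    long_mask = spans.values > 500_000
    drop = np.zeros(len(loop_df), dtype=bool)
    long_idx = np.flatnonzero(long_mask)
    n_drop = int(round(loop_drop_fraction * len(long_idx)))
    if n_drop:
        drop[rng.choice(long_idx, size=n_drop, replace=False)] = True
    loop_df["dropped"] = drop
    loop_df["score"] = 1.0

    # -- enhancers ---------------------------------------------------------
    enh_rows = []
    n_enh = int(round(total_bp / 1e6 * enhancers_per_mb))
    for i in range(n_enh):
        for attempt in range(max_place_retries):
            chrom = rng.choice(layout.chrom_names, p=chrom_probs)
            L = layout.lengths[chrom]
            start = int(rng.integers(0, L - enhancer_size_bp))
            end = start + enhancer_size_bp
            doms = dom_by_chrom[chrom]
            if len(doms) and np.any((doms[:, 0] < end) & (doms[:, 1] > start)):
                continue
            gi = gene_iv[chrom]
            if len(gi) and np.any((gi[:, 0] < end) & (gi[:, 1] > start)):
                continue
            enh_rows.append((chrom, start, end, f"enh{i + 1:04d}"))
            break
    # one enhancer at the centre of every planted loop anchor
    k = len(enh_rows)
    for _, r in loop_df.iterrows():
        for s, e in ((r["start1"], r["end1"]), (r["start2"], r["end2"])):
            mid = (s + e) // 2
            k += 1
            enh_rows.append((r["chrom"], mid - enhancer_size_bp // 2,
                             mid + enhancer_size_bp // 2, f"enh{k:04d}"))
    # keep placement order: intergenic enhancers first, anchor enhancers after
    enhancers = IntervalSet.from_records(enh_rows)

    # -- truth -------------------------------------------------------------
    target_ids: list[str] = []
    for _, r in loop_df[loop_df["dropped"]].iterrows():
        for s, e in ((r["start1"], r["end1"]), (r["start2"], r["end2"])):
            gid = nearest_gene(r["chrom"], int(s), int(e), genes)
            if gid is not None:
                target_ids.append(gid)
    loop_targets = tuple(dict.fromkeys(target_ids))
    expr_class = {}
    for gid, ind in zip(genes.df["gene_id"], in_domain_flags):
        cls = "up" if ind else "null"
        if gid in loop_targets:
            cls = "down" if not ind else "mixed"
        expr_class[gid] = cls
    truth = SyntheticTruth(
        master_seed=seed,
        domains=domains,
        domain_folds=domain_folds,
        genic_gain_coef=genic_gain_coef,
        loops=loop_df,
        loop_bin_size=loop_bin_size,
        loop_target_genes=loop_targets,
        expression_class=expr_class,
        layout=layout,
        genes=genes,
        enhancers=enhancers,
    )
    return layout, genes, enhancers, truth


# ----------------------------------------------------------------------
def _enrichment_profiles(
    truth: SyntheticTruth, bin_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Expected per-bin enrichment (fold over flat) for parental and treated."""
    layout, genes = truth.layout, truth.genes
    n = layout.total_bins(bin_size)
    probe = BinnedTrack(layout, bin_size, np.zeros(n), "count")
    parental = np.ones(n)
    for (_, dom), fold in zip(truth.domains.df.iterrows(), truth.domain_folds):
        w = probe.region_weights(
            IntervalSet.from_records([(dom["chrom"], dom["start"], dom["end"])])
        )
        parental += (fold - 1.0) * w
    treated = np.ones(n)
    offsets = layout.bin_offsets(bin_size)
    lengths = layout.lengths
    for _, g in genes.df.iterrows():
        wgt = truth.genic_gain_coef * math.log1p(g["baseline_fpkm"])
        if wgt <= 0:
            continue
        s, e = int(g["start"]), int(g["end"])
        off = offsets[g["chrom"]]
        b0, b1 = s // bin_size, (e - 1) // bin_size
        for b in range(b0, b1 + 1):
            bs = b * bin_size
            be = min(bs + bin_size, lengths[g["chrom"]])
            ov = min(be, e) - max(bs, s)
            treated[off + b] += wgt * ov / (be - bs)
    return parental, treated


def simulate_mark_tracks(
    truth: SyntheticTruth,
    bin_size: int = 100_000,
    depth_per_condition: float = 2e6,
    dispersion: float = 0.1,
    seed: int | None = None,
    *,
    n_replicates: int = 3,
    base_freq_pct: float = 5.0,
    input_noise_sd: float = 0.05,
    ms_replicates: int = 3,
    ms_noise_sd: float = 0.1,
    mark: str = "H3K9me3",
    poisson: bool = False,
) -> tuple[BinnedTrack, BinnedTrack, BinnedTrack, MSCalibration]:
    """Draw binned tag-count tracks for parental, treated and input.

    Each condition is sequenced as ``n_replicates`` biological replicates of
    ``depth_per_condition`` tags whose counts are pooled, mirroring the
    merged-replicate (n = 3) design of the emulated experiment.  Per-replicate
    counts are negative-binomial with mean depth * enrichment_i /
    sum(enrichment) and variance m + dispersion * m^2 (``poisson=True`` or
    dispersion 0 gives the Poisson limit).  The input control is a single
    library.  The MS percentages are the genome-wide means of the true
    per-bin modification frequencies (base_freq_pct * enrichment, capped at
    100), averaged over noisy pseudo-replicate measurements.
    """
    if depth_per_condition <= 0:
        raise GenomicsError("depth_per_condition must be > 0")
    if dispersion < 0:
        raise GenomicsError("dispersion must be >= 0")
    if n_replicates < 1:
        raise GenomicsError("n_replicates must be >= 1")
    master = truth.master_seed if seed is None else seed
    rng = np.random.default_rng(child_seed(master, "tracks"))
    layout = truth.layout
    parental_e, treated_e = _enrichment_profiles(truth, bin_size)

    def draw_one(enrich: np.ndarray, as_poisson: bool) -> np.ndarray:
        m = depth_per_condition * enrich / enrich.sum()
        if as_poisson:
            return rng.poisson(m).astype(float)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + m)).astype(float)

    def draw(enrich: np.ndarray, reps: int, as_poisson: bool) -> np.ndarray:
        return sum(draw_one(enrich, as_poisson) for _ in range(reps))

    chip_poisson = poisson or dispersion == 0
    parental = BinnedTrack(
        layout, bin_size, draw(parental_e, n_replicates, chip_poisson), "count"
    )
    treated = BinnedTrack(
        layout, bin_size, draw(treated_e, n_replicates, chip_poisson), "count"
    )
    # input has no IP-efficiency variance: Poisson counts on a mappability-
    # jittered flat profile
    input_e = np.exp(rng.normal(0.0, input_noise_sd, size=len(parental_e)))
    input_track = BinnedTrack(
        layout, bin_size, draw(input_e, 1, True), "count"
    )

    cal = {}
    for cond, enrich in (("parental", parental_e), ("treated", treated_e)):
        f = np.minimum(base_freq_pct * enrich, 100.0)
        true_pct = float(f.mean())
        truth.true_pct[cond] = true_pct
        reps = true_pct + rng.normal(0.0, ms_noise_sd, size=ms_replicates)
        cal[(mark, cond)] = float(np.clip(reps.mean(), 0.0, 100.0))
    return parental, treated, input_track, MSCalibration(cal)


# ----------------------------------------------------------------------
def simulate_contact_maps(
    truth: SyntheticTruth,
    bin_size: int = 100_000,
    decay_exponent: float = 1.0,
    compartment_contrast_parental: float = 1.0,
    compartment_contrast_treated: float = 0.3,
    loop_strength: float = 2.0,
    seed: int | None = None,
    *,
    mean_diag_count: float = 60.0,
) -> tuple[dict[str, dict[str, ContactMatrix]], dict[str, LoopSet]]:
    """Poisson contact maps with distance decay, checkerboard and loops.

    Expected contacts: mean_diag_count * (|i-j|+1)^-decay_exponent *
    (1 + contrast * same_compartment) * (1 + loop_strength at planted anchor
    pairs).  Compartment identity derives from the planted domains (domain =
    B); the treated condition uses the lower contrast and omits the flagged
    dropped loops.
    """
    if decay_exponent <= 0:
        raise GenomicsError("decay_exponent must be > 0")
    master = truth.master_seed if seed is None else seed
    rng = np.random.default_rng(child_seed(master, "contacts"))
    layout = truth.layout
    probe = BinnedTrack(layout, bin_size, np.zeros(layout.total_bins(bin_size)), "count")
    domain_frac = probe.region_weights(truth.domains)
    offsets = layout.bin_offsets(bin_size)
    n_bins = layout.n_bins(bin_size)

    contrasts = {
        "parental": compartment_contrast_parental,
        "treated": compartment_contrast_treated,
    }
    loops = truth.loops if truth.loops is not None else pd.DataFrame(
        columns=["chrom", "start1", "end1", "start2", "end2", "dropped", "score"]
    )
    matrices: dict[str, dict[str, ContactMatrix]] = {}
    loop_sets: dict[str, LoopSet] = {}
    for cond, contrast in contrasts.items():
        keep = loops if cond == "parental" else loops[~loops["dropped"]]
        per_chrom: dict[str, ContactMatrix] = {}
        for chrom in layout.chrom_names:
            n = n_bins[chrom]
            off = offsets[chrom]
            is_b = domain_frac[off: off + n] > 0.5
            same = is_b[:, None] == is_b[None, :]
            d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
            expected = mean_diag_count * (d + 1.0) ** (-decay_exponent)
            expected *= 1.0 + contrast * same
            sub = keep[keep["chrom"] == chrom]
            for _, r in sub.iterrows():
                i = int(r["start1"]) // bin_size
                j = int(r["start2"]) // bin_size
                if i < n and j < n:
                    expected[i, j] *= 1.0 + loop_strength
                    expected[j, i] = expected[i, j]
            upper = np.triu(rng.poisson(expected)).astype(float)
            mat = upper + np.triu(upper, 1).T
            per_chrom[chrom] = ContactMatrix(chrom, bin_size, mat)
        matrices[cond] = per_chrom
        loop_sets[cond] = LoopSet(
            keep[["chrom", "start1", "end1", "start2", "end2", "score"]]
            .reset_index(drop=True),
            truth.loop_bin_size,
        )
    return matrices, loop_sets


# ----------------------------------------------------------------------
def simulate_expression_response(
    truth: SyntheticTruth,
    effect_lfc: float = 2.0,
    noise_sd: float = 0.5,
    seed: int | None = None,
    *,
    loop_effect_lfc: float = 1.5,
) -> ExpressionDelta:
    """Per-gene log2FC with planted in-domain up-shift and loop-target
    down-shift, Gaussian noise, and BH-adjusted p-values on z-scores."""
    master = truth.master_seed if seed is None else seed
    rng = np.random.default_rng(child_seed(master, "expression"))
    genes = truth.genes
    dom_hit = genes.intervals().overlaps_any(truth.domains)
    targets = set(truth.loop_target_genes)
    mean = np.where(dom_hit, effect_lfc, 0.0)
    is_target = genes.df["gene_id"].isin(targets).values
    mean = mean - np.where(is_target, loop_effect_lfc, 0.0)
    lfc = mean + (rng.normal(0.0, noise_sd, size=len(genes)) if noise_sd > 0 else 0.0)
    if noise_sd > 0:
        z = lfc / noise_sd
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        p = np.where(lfc == 0.0, 1.0, 0.0)
    padj = _benjamini_hochberg(p)
    return ExpressionDelta(
        pd.DataFrame(
            {"gene_id": genes.df["gene_id"], "log2fc": lfc, "padj": padj,
             "baseline_fpkm": genes.df["baseline_fpkm"]}
        )
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out
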