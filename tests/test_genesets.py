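"""Bespoke gene-set constructions and shift counting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiredist.genesets import (
    build_large_enhancer_domains,
    build_matched_gene_sets,
    classify_accessible_cres,
    count_expression_shifts,
    gene_mark_change,
    intersect_replicate_peaks,
)
from epiredist.genome import BinnedTrack, GenomeLayout, GenomicsError, IntervalSet
from epiredist.simulate import simulate_mark_tracks
from epiredist.tables import ExpressionDelta, GeneTable
from epiredist.tracknorm import depth_normalize, ms_calibrate

LAYOUT = GenomeLayout(("chr1",), (1_000_000,))


def genes_from(rows):
    return GeneTable(
        pd.DataFrame(
            rows,
            columns=["gene_id", "chrom", "start", "end", "strand",
                     "baseline_fpkm", "raw_counts", "biotype"],
        )
    )


def deltas_from(pairs):
    return ExpressionDelta(
        pd.DataFrame(
            [{"gene_id": g, "log2fc": lfc, "padj": 0.5, "baseline_fpkm": 1.0}
             for g, lfc in pairs]
        )
    )


class TestLargeEnhancerDomains:
    ENH = IntervalSet.from_records([("chr1", 105_000, 106_000)])

    def test_surviving_peak_is_extended_both_sides(self):
        peaks = IntervalSet.from_records([("chr1", 100_000, 110_000)])
        out = build_large_enhancer_domains(peaks, [150.0], self.ENH, LAYOUT)
        assert out == IntervalSet.from_records([("chr1", 50_000, 160_000)])

    def test_count_filter_is_strictly_greater(self):
        peaks = IntervalSet.from_records([("chr1", 100_000, 110_000)])
        with pytest.warns(UserWarning):
            out = build_large_enhancer_domains(peaks, [100.0], self.ENH, LAYOUT)
        assert len(out) == 0

    def test_peak_without_enhancer_dropped(self):
        peaks = IntervalSet.from_records([("chr1", 500_000, 510_000)])
        with pytest.warns(UserWarning):
            out = build_large_enhancer_domains(peaks, [150.0], self.ENH, LAYOUT)
        assert len(out) == 0

    def test_extension_clamped_to_chromosome(self):
        peaks = IntervalSet.from_records([("chr1", 10_000, 20_000)])
        enh = IntervalSet.from_records([("chr1", 12_000, 13_000)])
        out = build_large_enhancer_domains(peaks, [200.0], enh, LAYOUT)
        assert out.df.loc[0, "start"] == 0

    def test_replicate_intersection(self):
        r1 = IntervalSet.from_records([("chr1", 0, 100), ("chr1", 500, 700)])
        r2 = IntervalSet.from_records([("chr1", 50, 120), ("chr1", 900, 950)])
        assert intersect_replicate_peaks([r1, r2]) == IntervalSet.from_records(
            [("chr1", 50, 100)]
        )
        with pytest.raises(GenomicsError):
            intersect_replicate_peaks([r1])


class TestMatchedGeneSets:
    def make_genes(self, n_in=10, n_out=50, fpkm=10.0):
        rows = []
        for i in range(n_in):
            rows.append((f"in{i}", "chr1", 10_000 + i * 5_000,
                         12_000 + i * 5_000, "+", fpkm, 100, "protein_coding"))
        for i in range(n_out):
            rows.append((f"out{i}", "chr1", 500_000 + i * 5_000,
                         502_000 + i * 5_000, "+", fpkm, 100, "protein_coding"))
        return genes_from(rows)

    DOMAINS = IntervalSet.from_records([("chr1", 0, 100_000)])

    def test_equal_sizes_and_reproducible(self):
        genes = self.make_genes()
        a = build_matched_gene_sets(genes, self.DOMAINS, seed=7)
        b = build_matched_gene_sets(genes, self.DOMAINS, seed=7)
        assert len(a.control) == len(a.in_domain) == 10
        assert a.control == b.control
        assert not set(a.control) & set(a.in_domain)

    def test_fpkm_window_boundary_excludes_below(self):
        rows = [("lo", "chr1", 10_000, 12_000, "+", 8.9, 10, "protein_coding"),
                ("ok", "chr1", 20_000, 22_000, "+", 9.0, 10, "protein_coding"),
                ("c1", "chr1", 500_000, 502_000, "+", 10.0, 10, "protein_coding")]
        m = build_matched_gene_sets(genes_from(rows), self.DOMAINS, seed=0)
        assert m.in_domain == ("ok",)

    def test_empty_domains_rejected(self):
        with pytest.raises(GenomicsError):
            build_matched_gene_sets(self.make_genes(), IntervalSet.empty(), seed=0)

    def test_small_control_pool_rejected_with_counts(self):
        genes = self.make_genes(n_in=10, n_out=3)
        with pytest.raises(GenomicsError, match="3"):
            build_matched_gene_sets(genes, self.DOMAINS, seed=0)

    def test_control_means_unbiased_over_seeds(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(20):
            rows.append((f"in{i}", "chr1", 10_000 + i * 4_000, 12_000 + i * 4_000,
                         "+", float(rng.uniform(9, 12)), 10, "protein_coding"))
        for i in range(200):
            rows.append((f"out{i}", "chr1", 200_000 + i * 3_000, 202_000 + i * 3_000,
                         "+", float(rng.uniform(9, 12)), 10, "protein_coding"))
        genes = genes_from(rows)
        fpkm = genes.df.set_index("gene_id")["baseline_fpkm"]
        diffs = []
        for seed in range(100):
            m = build_matched_gene_sets(genes, self.DOMAINS, seed=seed)
            diffs.append(fpkm[list(m.control)].mean() - fpkm[list(m.in_domain)].mean())
        assert abs(np.mean(diffs)) < (12 - 9) / 4


class TestCountShifts:
    def test_sign_based_counts(self):
        deltas = deltas_from([("a", 1.0), ("b", -1.0), ("c", -2.0), ("d", 0.5)])
        sa, _ = count_expression_shifts(["a", "b", "c"], ["d"], deltas)
        assert (sa.n_up, sa.n_down, sa.n_zero) == (1, 2, 0)
        assert sa.n == 3

    def test_all_zero_lfcs(self):
        deltas = deltas_from([("a", 0.0), ("b", 0.0), ("c", 1.0)])
        sa, _ = count_expression_shifts(["a", "b"], ["c"], deltas)
        assert (sa.n_up, sa.n_down, sa.n_zero) == (0, 0, 2)

    def test_identical_sets_give_ranksum_p_of_one(self):
        deltas = deltas_from([("a", 1.0), ("b", -0.5), ("c", 2.0)])
        sa, sb = count_expression_shifts(["a", "b", "c"], ["a", "b", "c"], deltas)
        assert sa.pvalue >= 0.99
        assert sa.stat == pytest.approx(0.0)

    def test_missing_genes_excluded_with_warning(self):
        deltas = deltas_from([("a", 1.0)])
        with pytest.warns(UserWarning, match="lack expression"):
            sa, _ = count_expression_shifts(["a", "ghost"], ["a"], deltas)
        assert sa.n == 1

    def test_empty_set_rejected(self):
        with pytest.raises(GenomicsError):
            count_expression_shifts([], ["a"], deltas_from([("a", 1.0)]))


class TestClassifyCres:
    GENES = genes_from(
        [("g1", "chr1", 100_000, 120_000, "+", 1.0, 10, "protein_coding"),
         ("g2", "chr1", 500_000, 520_000, "-", 1.0, 10, "protein_coding")]
    )

    def peaks(self, *recs):
        return IntervalSet.from_records([("chr1", s, e) for s, e in recs])

    def test_distal_shared_peak_is_enhancer(self):
        shared = self.peaks((200_000, 201_000))
        enh, prom = classify_accessible_cres(shared, shared, self.GENES)
        assert len(enh) == 1 and len(prom) == 0

    def test_tss_peak_is_promoter_not_enhancer(self):
        shared = self.peaks((99_500, 100_500))
        enh, prom = classify_accessible_cres(shared, shared, self.GENES)
        assert len(prom) == 1 and len(enh) == 0

    def test_peak_2_9kb_away_is_neither(self):
        shared = self.peaks((102_900, 103_400))  # inside gene, 2.9 kb from TSS
        enh, prom = classify_accessible_cres(shared, shared, self.GENES)
        assert len(enh) == 0 and len(prom) == 0

    def test_minus_strand_promoter_window_is_strand_aware(self):
        # g2 TSS at 519_999; promoter window reaches 1500 bp upstream (right)
        shared = self.peaks((520_800, 521_000))
        enh, prom = classify_accessible_cres(shared, shared, self.GENES)
        assert len(prom) == 1
        # ... but 1500 bp past the TSS on the downstream (left) side is not
        shared = self.peaks((518_000, 518_200))
        enh, prom = classify_accessible_cres(shared, shared, self.GENES)
        assert len(prom) == 0

    def test_only_shared_peaks_are_considered(self):
        a = self.peaks((200_000, 201_000))
        b = self.peaks((300_000, 301_000))
        enh, prom = classify_accessible_cres(a, b, self.GENES)
        assert len(enh) == 0 and len(prom) == 0

    def test_enhancers_never_touch_tss_windows(self):
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 990_000, 200)
        shared = IntervalSet.from_records(
            [("chr1", int(s), int(s) + 1000) for s in starts]
        )
        enh, _ = classify_accessible_cres(shared, shared, self.GENES)
        tss_windows = IntervalSet.from_records(
            [("chr1", 97_000, 103_001), ("chr1", 516_999, 523_000)]
        )
        assert not enh.overlaps_any(tss_windows).any()


class TestGeneMarkChange:
    def tracks(self, parental_vals, treated_vals):
        p = BinnedTrack(LAYOUT, 100_000, np.array(parental_vals, float), "ms_percent")
        t = BinnedTrack(LAYOUT, 100_000, np.array(treated_vals, float), "ms_percent")
        return p, t

    GENES = genes_from(
        [("g1", "chr1", 100_000, 200_000, "+", 1.0, 10, "protein_coding")]
    )

    def test_equal_signal_gives_zero(self):
        p, t = self.tracks([2.0] * 10, [2.0] * 10)
        out = gene_mark_change(p, t, self.GENES)
        assert out.loc[0, "log2fc"] == 0.0

    def test_doubling_approaches_plus_one_as_pseudocount_vanishes(self):
        p, t = self.tracks([2.0] * 10, [4.0] * 10)
        out = gene_mark_change(p, t, self.GENES, pseudocount=1e-12)
        assert out.loc[0, "log2fc"] == pytest.approx(1.0, abs=1e-9)

    def test_planted_domain_genes_classified_as_loss(self, default_bundle):
        """>= 90% of genes inside planted lost domains lose the mark."""
        b = default_bundle
        pct = b["cal"]
        p_ms = ms_calibrate(
            depth_normalize(b["parental"], float(b["parental"].values.sum())),
            pct.pct("H3K9me3", "parental"),
        )
        t_ms = ms_calibrate(
            depth_normalize(b["treated"], float(b["treated"].values.sum())),
            pct.pct("H3K9me3", "treated"),
        )
        out = gene_mark_change(p_ms, t_ms, b["genes"])
        in_domain = b["genes"].intervals().overlaps_any(b["truth"].domains)
        sub = out[in_domain]
        assert len(sub) > 0
        assert (sub["log2fc"] < 0).mean() >= 0.9
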