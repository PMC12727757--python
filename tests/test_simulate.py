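"""Generator contracts: determinism, planted-parameter recovery, limits."""

import numpy as np
import pytest

from epiredist.compartments import compartment_score, oe_transform, saddle_strength
from epiredist.genome import BinnedTrack, GenomicsError
from epiredist.simulate import (
    child_seed,
    make_genome_annotation,
    simulate_contact_maps,
    simulate_expression_response,
    simulate_mark_tracks,
)


def domain_mask(truth, bin_size=100_000):
    layout = truth.layout
    probe = BinnedTrack(layout, bin_size, np.zeros(layout.total_bins(bin_size)),
                        "count")
    return probe.region_weights(truth.domains) > 0.5


class TestGenomeAnnotation:
    def test_deterministic_under_fixed_seed(self):
        a = make_genome_annotation(seed=1)
        b = make_genome_annotation(seed=1)
        assert a[0] == b[0]
        assert a[1].df.equals(b[1].df)
        assert a[2] == b[2]
        assert a[3].domains == b[3].domains
        assert a[3].loops.equals(b[3].loops)

    def test_default_scale_yields_200_genes(self):
        _, genes, _, _ = make_genome_annotation(seed=1)
        assert len(genes) == 200

    def test_domain_fraction_measured_over_seeds(self):
        fracs = []
        for seed in range(10):
            layout, _, _, truth = make_genome_annotation(
                seed=seed, domain_fraction=0.25
            )
            fracs.append(truth.domains.total_bp / layout.total_bp)
        assert all(0.2 <= f <= 0.3 for f in fracs)

    def test_zero_domain_fraction_gives_empty_set(self):
        _, _, _, truth = make_genome_annotation(seed=2, domain_fraction=0.0)
        assert len(truth.domains) == 0

    def test_infeasible_density_errors(self):
        with pytest.raises(GenomicsError, match="density|place"):
            make_genome_annotation(
                n_chrom=1, chrom_length_bp=1_000_000, gene_density=2000,
                domain_fraction=0.0, seed=0, max_place_retries=20,
            )

    def test_enhancers_avoid_gene_bodies_except_anchor_placements(self):
        _, genes, enhancers, truth = make_genome_annotation(seed=3)
        anchor_names = set()
        n_base = len(enhancers) - 2 * len(truth.loops)
        base = enhancers.df.iloc[:n_base]
        from epiredist.genome import IntervalSet

        base_set = IntervalSet(base)
        assert not base_set.overlaps_any(genes.intervals()).any()


class TestMarkTracks:
    def test_parental_domain_fold_recovered(self):
        """Monte-Carlo check of the generator against its own parameters."""
        layout, _, _, truth = make_genome_annotation(
            n_chrom=2, chrom_length_bp=25_000_000, gene_density=5.0,
            domain_fraction=0.4, seed=7, domain_fold=8.0,
        )
        parental, _, _, _ = simulate_mark_tracks(
            truth, depth_per_condition=1e6, seed=7
        )
        mask = domain_mask(truth)
        ratio = parental.values[mask].mean() / parental.values[~mask].mean()
        assert 6.0 <= ratio <= 10.0

    def test_treated_domains_fall_to_background(self):
        _, _, _, truth = make_genome_annotation(seed=5)
        _, treated, _, _ = simulate_mark_tracks(truth, seed=5)
        mask = domain_mask(truth)
        ratio = treated.values[mask].mean() / treated.values[~mask].mean()
        assert 0.6 <= ratio <= 1.3

    def test_high_expression_genic_bins_gain_in_treated(self):
        _, genes, _, truth = make_genome_annotation(seed=6)
        parental, treated, _, _ = simulate_mark_tracks(truth, seed=6)
        high = genes.df[genes.df["baseline_fpkm"] > 20]
        probe = BinnedTrack(truth.layout, 100_000,
                            np.zeros(truth.layout.total_bins(100_000)), "count")
        from epiredist.genome import IntervalSet

        w = probe.region_weights(IntervalSet(high[["chrom", "start", "end"]]))
        genic = (w > 0.2) & ~domain_mask(truth)
        assert genic.sum() >= 5
        assert treated.values[genic].mean() > parental.values[genic].mean()

    def test_poisson_flag_variance_matches_mean(self):
        layout, _, _, truth = make_genome_annotation(
            n_chrom=1, chrom_length_bp=100_000_000, gene_density=0.0,
            domain_fraction=0.0, seed=8, loops_per_chrom=0,
        )
        track, _, _, _ = simulate_mark_tracks(
            truth, bin_size=10_000, depth_per_condition=5e6, seed=8, poisson=True
        )
        # 1e4 flat bins: variance/mean ~ 1 within 10%
        assert len(track.values) == 10_000
        vm = track.values.var() / track.values.mean()
        assert 0.9 <= vm <= 1.1

    def test_ms_percentages_consistent_with_simulated_means(self):
        _, _, _, truth = make_genome_annotation(seed=9)
        _, _, _, cal = simulate_mark_tracks(truth, seed=9)
        for cond in ("parental", "treated"):
            assert cal.pct("H3K9me3", cond) == pytest.approx(
                truth.true_pct[cond], abs=0.5
            )

    def test_nonpositive_depth_rejected(self):
        _, _, _, truth = make_genome_annotation(seed=1)
        with pytest.raises(GenomicsError):
            simulate_mark_tracks(truth, depth_per_condition=0)


class TestContactMaps:
    def test_matrices_symmetric_and_loop_sets_nested(self):
        _, _, _, truth = make_genome_annotation(seed=4)
        matrices, loop_sets = simulate_contact_maps(truth)
        for cond in ("parental", "treated"):
            for m in matrices[cond].values():
                np.testing.assert_array_equal(m.matrix, m.matrix.T)
        par = {(r["chrom"], r["start1"], r["start2"])
               for _, r in loop_sets["parental"].df.iterrows()}
        tre = {(r["chrom"], r["start1"], r["start2"])
               for _, r in loop_sets["treated"].df.iterrows()}
        assert tre < par
        n_dropped = int(truth.loops["dropped"].sum())
        assert len(par) - len(tre) == n_dropped

    def test_zero_contrast_strength_near_one(self):
        """With no planted compartment contrast, the saddle statistic at the
        planted partition is ~1.  (Eigenvector scores are deliberately not
        used here: fitted on pure noise they overfit the same cells the
        saddle averages and bias the ratio.)"""
        from epiredist.compartments import CompartmentTrack

        _, _, _, truth = make_genome_annotation(seed=10)
        matrices, _ = simulate_contact_maps(
            truth, compartment_contrast_parental=0.0,
            compartment_contrast_treated=0.0,
        )
        layout = truth.layout
        probe = BinnedTrack(layout, 100_000,
                            np.zeros(layout.total_bins(100_000)), "count")
        dom = probe.region_weights(truth.domains)
        off = layout.bin_offsets(100_000)
        nb = layout.n_bins(100_000)
        rng = np.random.default_rng(99)
        strengths = []
        for chrom, m in matrices["parental"].items():
            sc = np.where(dom[off[chrom]: off[chrom] + nb[chrom]] > 0.5,
                          -1.0, 1.0) + rng.normal(0, 0.01, m.n)
            res = saddle_strength(
                oe_transform(m), CompartmentTrack(chrom, 100_000, sc)
            )
            strengths += [res.strength_aa, res.strength_bb]
        assert all(0.8 <= s <= 1.25 for s in strengths)

    def test_invalid_decay_rejected(self):
        _, _, _, truth = make_genome_annotation(seed=1)
        with pytest.raises(GenomicsError):
            simulate_contact_maps(truth, decay_exponent=0.0)


class TestExpressionResponse:
    def test_planted_updirection_recovered(self):
        layout, genes, _, truth = make_genome_annotation(
            seed=3, gene_density=10.0, domain_fraction=0.4,
            domain_gene_bias=0.0, silent_fraction_in_domain=0.25,
        )
        deltas = simulate_expression_response(truth, effect_lfc=2.0, noise_sd=0.5)
        in_dom = genes.intervals().overlaps_any(truth.domains)
        in_ids = set(genes.df["gene_id"][in_dom]) - set(truth.loop_target_genes)
        sub = deltas.df[deltas.df["gene_id"].isin(in_ids)]
        assert len(sub) >= 100
        assert (sub["log2fc"] > 0).mean() >= 0.9

    def test_zero_effect_is_sign_symmetric(self):
        _, genes, _, truth = make_genome_annotation(seed=12)
        deltas = simulate_expression_response(
            truth, effect_lfc=0.0, noise_sd=0.5, loop_effect_lfc=0.0
        )
        in_dom = genes.intervals().overlaps_any(truth.domains)
        sub = deltas.df[in_dom.tolist()]
        n, k = len(sub), int((sub["log2fc"] > 0).sum())
        assert abs(k - n / 2) < 3 * np.sqrt(n * 0.25)

    def test_zero_noise_gives_exact_effects(self):
        _, genes, _, truth = make_genome_annotation(seed=13)
        deltas = simulate_expression_response(
            truth, effect_lfc=2.0, noise_sd=0.0, loop_effect_lfc=0.0
        )
        in_dom = genes.intervals().overlaps_any(truth.domains)
        np.testing.assert_array_equal(
            deltas.df["log2fc"][in_dom.tolist()].values, 2.0
        )
        np.testing.assert_array_equal(
            deltas.df["log2fc"][(~in_dom).tolist()].values, 0.0
        )


class TestSeedFanout:
    def test_components_get_distinct_reproducible_streams(self):
        a = np.random.default_rng(child_seed(5, "tracks")).uniform(size=3)
        b = np.random.default_rng(child_seed(5, "tracks")).uniform(size=3)
        c = np.random.default_rng(child_seed(5, "contacts")).uniform(size=3)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)
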