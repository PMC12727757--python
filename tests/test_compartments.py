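"""O/E transform, compartment scores, saddle strength, range fractions."""

import numpy as np
import pandas as pd
import pytest

from epiredist.compartments import (
    CompartmentTrack,
    ContactMatrix,
    cis_range_fractions,
    compartment_score,
    compartment_shift_counts,
    oe_transform,
    read_coo_matrix,
    read_dense_matrix,
    saddle_strength,
    write_coo_matrix,
    write_dense_matrix,
)
from epiredist.genome import GenomicsError


def checkerboard(n=40, within=2.0, cross=0.5, block=5):
    """Alternating-block matrix whose O/E is exactly within/cross."""
    comp = (np.arange(n) // block) % 2
    same = comp[:, None] == comp[None, :]
    return np.where(same, within, cross), comp


class TestOETransform:
    def test_matrix_equal_to_diagonal_means_becomes_ones(self):
        n = 6
        base = np.fromfunction(lambda i, j: 1.0 / (np.abs(i - j) + 1), (n, n))
        oe = oe_transform(ContactMatrix("chr1", 10, base))
        np.testing.assert_allclose(oe.matrix, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.gamma(2.0, 1.0, (8, 8))
        m = (a + a.T) / 2
        oe1 = oe_transform(ContactMatrix("chr1", 10, m))
        oe2 = oe_transform(ContactMatrix("chr1", 10, 2.0 * m))
        np.testing.assert_allclose(oe1.matrix, oe2.matrix)

    def test_hand_computed_4x4(self):
        m = np.array(
            [[4.0, 2.0, 1.0, 0.0],
             [2.0, 8.0, 4.0, 1.0],
             [1.0, 4.0, 4.0, 2.0],
             [0.0, 1.0, 2.0, 4.0]]
        )
        oe = oe_transform(ContactMatrix("chr1", 10, m))
        # diagonal means: d0 = 5, d1 = 8/3, d2 = 1, d3 = 0
        expected_d0 = np.diag(m) / 5.0
        np.testing.assert_allclose(np.diag(oe.matrix), expected_d0)
        assert oe.matrix[0, 1] == pytest.approx(2.0 / (8.0 / 3.0))
        assert oe.matrix[0, 2] == pytest.approx(1.0)
        assert oe.matrix[0, 3] == 0.0  # zero expected -> masked to 0

    def test_asymmetric_rejected(self):
        m = np.array([[1.0, 2.0], [3.0, 1.0]])
        with pytest.raises(GenomicsError):
            ContactMatrix("chr1", 10, m)

    def test_all_masked_rejected(self):
        m = ContactMatrix("chr1", 10, np.ones((3, 3)), bad_bins=[True] * 3)
        with pytest.raises(GenomicsError):
            oe_transform(m)


class TestCompartmentScore:
    def test_two_block_matrix_separates_signs(self):
        mat, comp = checkerboard()
        m = ContactMatrix("chr1", 10, mat)
        score = compartment_score(m, phasing=np.where(comp == 0, 1.0, -1.0))
        s = score.scores
        assert (np.sign(s[comp == 0]) != np.sign(s[comp == 1])).all()

    def test_phasing_sign_convention(self):
        mat, comp = checkerboard()
        m = ContactMatrix("chr1", 10, mat)
        ph = np.where(comp == 0, 1.0, -1.0)
        up = compartment_score(m, ph).scores
        down = compartment_score(m, -ph).scores
        np.testing.assert_allclose(up, -down, atol=1e-12)
        assert np.corrcoef(up[np.isfinite(up)], ph)[0, 1] >= 0

    def test_constant_matrix_is_degenerate(self):
        m = ContactMatrix("chr1", 10, np.full((6, 6), 3.0))
        with pytest.raises(GenomicsError):
            compartment_score(m, np.arange(6.0))


class TestSaddleStrength:
    def test_analytic_checkerboard_gives_exactly_four(self):
        mat, comp = checkerboard(within=2.0, cross=0.5)
        oe = ContactMatrix("chr1", 10, mat)
        scores = CompartmentTrack("chr1", 10, np.where(comp == 0, 1.0, -1.0))
        for mode in ("saddle-corner", "global-bottom"):
            res = saddle_strength(oe, scores, q=0.20, ab_mode=mode)
            assert res.strength_aa == pytest.approx(4.0)
            assert res.strength_bb == pytest.approx(4.0)

    def test_invalid_quantile_rejected(self):
        mat, comp = checkerboard()
        oe = ContactMatrix("chr1", 10, mat)
        scores = CompartmentTrack("chr1", 10, comp.astype(float))
        with pytest.raises(GenomicsError):
            saddle_strength(oe, scores, q=0.6)

    def test_random_matrix_strengths_near_one(self):
        strengths = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = rng.normal(1.0, 0.2, (200, 200))
            oe_mat = np.clip((a + a.T) / 2, 0.05, None)
            oe = ContactMatrix("chr1", 10, oe_mat)
            scores = CompartmentTrack("chr1", 10, rng.normal(size=200))
            res = saddle_strength(oe, scores)
            strengths += [res.strength_aa, res.strength_bb]
        assert min(strengths) > 0.9 and max(strengths) < 1.1

    def test_strength_invariant_to_uniform_scaling_and_relabeling(self):
        mat, comp = checkerboard(n=30, block=3)
        rng = np.random.default_rng(4)
        noise = rng.gamma(20.0, 0.05, (30, 30))
        mat = mat * (noise + noise.T) / 2
        scores = np.where(comp == 0, 1.0, -1.0) + rng.normal(0, 0.01, 30)
        r1 = saddle_strength(ContactMatrix("chr1", 10, mat),
                             CompartmentTrack("chr1", 10, scores))
        r2 = saddle_strength(ContactMatrix("chr1", 10, 7.0 * mat),
                             CompartmentTrack("chr1", 10, scores))
        perm = rng.permutation(30)
        r3 = saddle_strength(
            ContactMatrix("chr1", 10, mat[np.ix_(perm, perm)]),
            CompartmentTrack("chr1", 10, scores[perm]),
        )
        assert r1.strength_aa == pytest.approx(r2.strength_aa)
        assert r1.strength_aa == pytest.approx(r3.strength_aa)
        assert r1.strength_bb == pytest.approx(r3.strength_bb)

    def test_masked_bins_excluded(self):
        mat, comp = checkerboard()
        mat[0, :] = mat[:, 0] = 1e6  # corrupt one bin, then mask it
        bad = np.zeros(len(comp), bool)
        bad[0] = True
        oe = ContactMatrix("chr1", 10, mat, bad_bins=bad)
        scores = CompartmentTrack("chr1", 10, np.where(comp == 0, 1.0, -1.0))
        res = saddle_strength(oe, scores)
        assert res.strength_aa == pytest.approx(4.0)


class TestCisRangeFractions:
    def pairs(self, rows):
        return pd.DataFrame(rows, columns=["separation", "count"])

    def test_all_long(self):
        fl, fs = cis_range_fractions(self.pairs([(20_000_000, 10.0)]))
        assert (fl, fs) == (1.0, 0.0)

    def test_all_short(self):
        fl, fs = cis_range_fractions(self.pairs([(5_000_000, 10.0)]))
        assert (fl, fs) == (0.0, 1.0)

    def test_sub_kilobase_contacts_excluded(self):
        fl, fs = cis_range_fractions(
            self.pairs([(500, 1.0), (5_000_000, 1.0), (20_000_000, 1.0)])
        )
        assert fl == pytest.approx(0.5)
        assert fs == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(GenomicsError):
            cis_range_fractions(self.pairs([(500, 1.0)]))


class TestShiftCounts:
    def test_identical_scores_have_no_switches(self):
        s = np.array([1.0, -1.0, 2.0])
        out = compartment_shift_counts(s, s)
        assert out["A->B"] == 0 and out["B->A"] == 0

    def test_negation_switches_every_bin(self):
        s = np.array([1.0, -1.0, 2.0])
        out = compartment_shift_counts(s, -s)
        assert out["A->B"] == 2 and out["B->A"] == 1

    def test_hand_vector(self):
        out = compartment_shift_counts(np.array([1.0, 1.0, -1.0]),
                                       np.array([1.0, -1.0, -1.0]))
        assert out == {"A->A": 1, "A->B": 1, "B->A": 0, "B->B": 1, "zero": 0}

    def test_length_mismatch_rejected(self):
        with pytest.raises(GenomicsError):
            compartment_shift_counts(np.ones(3), np.ones(4))


class TestMatrixIO:
    def test_dense_and_coo_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        a = rng.poisson(3.0, (12, 12)).astype(float)
        m = ContactMatrix("chr2", 50_000, (a + a.T) / 2)
        p = tmp_path / "m.tsv"
        write_dense_matrix(m, p)
        back = read_dense_matrix(p)
        assert back.chrom == "chr2" and back.bin_size == 50_000
        np.testing.assert_array_equal(back.matrix, m.matrix)
        p = tmp_path / "m.coo.tsv"
        write_coo_matrix(m, p)
        back = read_coo_matrix(p)
        np.testing.assert_array_equal(back.matrix, m.matrix)
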