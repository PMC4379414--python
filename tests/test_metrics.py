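"""Segmentation-metric unit and property tests against definition oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wristseg.metrics import (ConfusionCounts, auc, confusion_counts, evaluate,
                              mad, majority_vote, mean_similarity,
                              opening_by_diamond, pattern_spectrum, xor_mask)
from conftest import mad_oracle, pattern_spectrum_oracle


def bool_mask(shape, seed):
    return np.random.default_rng(seed).random(shape) < 0.4


class TestConfusionCounts:
    def test_identity_masks_have_no_errors(self):
        m = bool_mask((6, 6), 0)
        c = confusion_counts(m, m)
        assert c.fp == 0 and c.fn == 0
        assert c.tp == m.sum() and c.total == m.size

    def test_complement_has_no_agreements(self):
        m = bool_mask((6, 6), 1)
        c = confusion_counts(m, ~m)
        assert c.tp == 0 and c.tn == 0

    def test_counts_match_exhaustive_enumeration(self):
        gt = bool_mask((4, 4), 2)
        seg = bool_mask((4, 4), 3)
        c = confusion_counts(gt, seg)
        tp = fp = tn = fn = 0
        for i in range(4):
            for j in range(4):
                if gt[i, j] and seg[i, j]:
                    tp += 1
                elif gt[i, j]:
                    fn += 1
                elif seg[i, j]:
                    fp += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestAuc:
    def test_ideal_classifier_scores_one(self):
        assert auc(ConfusionCounts(tp=10, fn=0, fp=0, tn=10)) == 1.0

    @pytest.mark.parametrize("t", [0.0, 0.1, 0.3, 0.5, 0.7, 1.0])
    def test_chance_diagonal_scores_half(self, t):
        assert auc(fpr=t, tpr=t) == pytest.approx(0.5)

    def test_matches_trapezoidal_integration(self):
        # area under the polyline {(0,0), (0.2,0.8), (1,1)}
        expected = np.trapezoid([0.0, 0.8, 1.0], [0.0, 0.2, 1.0])
        assert auc(fpr=0.2, tpr=0.8) == pytest.approx(expected) == pytest.approx(0.8)

    def test_undefined_rates_raise(self):
        with pytest.raises(ValueError):
            auc(ConfusionCounts(tp=0, fn=0, fp=1, tn=1))  # no positives
        with pytest.raises(ValueError):
            auc(ConfusionCounts(tp=1, fn=1, fp=0, tn=0))  # no negatives


class TestMeanSimilarity:
    def test_identical_masks(self):
        m = bool_mask((5, 5), 4)
        assert mean_similarity(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = b[3, 3] = True
        assert mean_similarity(a, b) == 0.0

    def test_shifted_block_is_one_third(self):
        a = np.zeros((4, 6), bool)
        b = np.zeros((4, 6), bool)
        a[1:3, 1:3] = True
        b[1:3, 2:4] = True  # overlap 2, union 6
        assert mean_similarity(a, b) == pytest.approx(1 / 3)

    def test_symmetry(self):
        a, b = bool_mask((8, 8), 5), bool_mask((8, 8), 6)
        assert mean_similarity(a, b) == mean_similarity(b, a)

    def test_both_empty_raises(self):
        with pytest.raises(ValueError):
            mean_similarity(np.zeros((3, 3), bool), np.zeros((3, 3), bool))


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
def test_xor_mask_truth_table(bits_a, bits_b):
    a = np.array([(bits_a >> i) & 1 for i in range(16)], bool).reshape(4, 4)
    b = np.array([(bits_b >> i) & 1 for i in range(16)], bool).reshape(4, 4)
    x = xor_mask(a, b)
    assert np.array_equal(x, (a & ~b) | (b & ~a))
    assert np.array_equal(x, xor_mask(b, a))


class TestPatternSpectrum:
    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert pattern_spectrum(m) == {1: 1}

    def test_three_by_three_square(self):
        m = np.zeros((7, 7), bool)
        m[2:5, 2:5] = True
        assert pattern_spectrum(m) == {1: 4, 2: 5}

    def test_empty_mask(self):
        assert pattern_spectrum(np.zeros((4, 4), bool)) == {}

    def test_mass_conservation(self):
        m = bool_mask((12, 12), 7)
        assert sum(pattern_spectrum(m).values()) == m.sum()

    def test_matches_oracle_on_all_3x3_masks(self):
        for bits in range(512):
            m = np.array([(bits >> i) & 1 for i in range(9)], bool).reshape(3, 3)
            assert pattern_spectrum(m) == pattern_spectrum_oracle(m), bits

    def test_opening_methods_agree(self):
        m = bool_mask((16, 16), 8)
        for n in (1, 2, 3):
            assert np.array_equal(opening_by_diamond(m, n, "iterated"),
                                  opening_by_diamond(m, n, "structuring"))


class TestMad:
    def test_identical_masks_by_convention(self):
        m = bool_mask((6, 6), 9)
        assert mad(m, m) == 0.0

    def test_isolated_pixel_difference(self):
        a = np.zeros((5, 5), bool)
        b = a.copy()
        b[2, 2] = True
        assert mad(a, b) == 1.0

    def test_three_by_three_difference(self):
        a = np.zeros((7, 7), bool)
        b = a.copy()
        b[2:5, 2:5] = True
        assert mad(a, b) == pytest.approx(14 / 9)

    @pytest.mark.parametrize("k,expected", [(1, 1.0), (2, 1.0), (3, 2.0)])
    def test_dilated_rectangle_mad_is_band_radius(self, k, expected):
        # the XOR of a rectangle and its k-fold diamond dilation is a band of
        # city-block width k, removed entirely at opening size ceil(k/2):
        # granulometric MAD measures the band radius, not its full width
        from scipy import ndimage
        rect = np.zeros((40, 46), bool)
        rect[8:32, 8:38] = True
        dil = ndimage.binary_dilation(
            rect, structure=ndimage.generate_binary_structure(2, 1), iterations=k)
        assert mad(rect, dil) == pytest.approx(expected, abs=0.2)
        assert expected == np.ceil(k / 2)

    def test_symmetry(self):
        a, b = bool_mask((10, 10), 10), bool_mask((10, 10), 11)
        assert mad(a, b) == mad(b, a)

    def test_modes_agree_on_z_constant_masks(self):
        # a column-wise constant 3D mask has the same 2D and 3D XOR geometry
        a = np.zeros((8, 8, 3), bool)
        b = a.copy()
        b[2:5, 2:5, :] = True
        assert mad(a, b, mode="per-slice") == pytest.approx(mad(a, b, mode="3d"), abs=0.8)


class TestMajorityVote:
    def test_unanimous(self):
        m = bool_mask((5, 5), 12)
        assert np.array_equal(majority_vote([m] * 5), m)

    def test_two_of_three_wins(self):
        a = np.zeros((3, 3), bool)
        b = a.copy()
        b[1, 1] = True
        assert majority_vote([b, b, a])[1, 1]

    def test_two_of_five_loses(self):
        a = np.zeros((3, 3), bool)
        b = a.copy()
        b[1, 1] = True
        assert not majority_vote([b, b, a, a, a])[1, 1]

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestEvaluate:
    def test_perfect_segmentation(self):
        gt = np.zeros((10, 10, 8), np.uint8)
        gt[2:5, 2:5, 2:5] = 1
        gt[6:9, 6:9, 2:5] = 2
        rep = evaluate(gt, gt)
        assert (rep.per_label["auc"] == 1.0).all()
        assert (rep.per_label["ms"] == 1.0).all()
        assert (rep.per_label["mad"] == 0.0).all()

    def test_dilated_label_has_unit_mad(self):
        from scipy import ndimage
        gt = np.zeros((24, 24, 18), np.uint8)
        gt[6:18, 6:18, 5:13] = 1
        seg = ndimage.binary_dilation(
            gt > 0, structure=ndimage.generate_binary_structure(3, 1)).astype(np.uint8)
        rep = evaluate(gt, seg)
        assert rep.per_label.iloc[0]["mad"] == pytest.approx(1.0, abs=0.1)

    def test_matches_per_label_brute_force(self):
        rng = np.random.default_rng(13)
        gt = rng.integers(0, 3, (8, 8, 6)).astype(np.uint8)
        seg = rng.integers(0, 3, (8, 8, 6)).astype(np.uint8)
        rep = evaluate(gt, seg)
        for label in (1, 2):
            row = rep.per_label[rep.per_label["label"] == label].iloc[0]
            assert row["ms"] == pytest.approx(
                mean_similarity(gt == label, seg == label))
            assert row["mad"] == pytest.approx(mad_oracle(gt == label, seg == label))

    def test_missing_label_reported_not_raised(self):
        gt = np.zeros((6, 6, 4), np.uint8)
        gt[1:3, 1:3, 1:3] = 1
        gt[4:6, 4:6, 1:3] = 2
        seg = np.where(gt == 2, 0, gt).astype(np.uint8)
        rep = evaluate(gt, seg)
        row = rep.per_label[rep.per_label["label"] == 2].iloc[0]
        assert bool(row["missing"])
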