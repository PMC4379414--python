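"""Low-level imaging primitive tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wristseg.imaging import (StructuringElement, connected_components,
                              fill_holes_2d, gradient_magnitude, keep_largest,
                              max_entropy_threshold, morph, smooth_histogram)
from conftest import kapur_oracle


def rand_mask(shape, seed, p=0.5):
    return np.random.default_rng(seed).random(shape) < p


class TestMorph:
    def test_close_preserves_se_shaped_sets(self):
        m = np.zeros((7, 7), bool)
        m[3, 3] = True
        se = StructuringElement("square", 1)
        assert np.array_equal(morph(m, "close", se), m)

    def test_erode_square_by_diamond_leaves_center(self):
        m = np.zeros((7, 7), bool)
        m[2:5, 2:5] = True
        out = morph(m, "erode", StructuringElement("diamond", 1))
        expected = np.zeros_like(m)
        expected[3, 3] = True
        assert np.array_equal(out, expected)

    def test_dilate_pixel_to_diamond(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        out = morph(m, "dilate", StructuringElement("diamond", 1))
        assert out.sum() == 5 and out[2, 2] and out[1, 2] and out[2, 1]

    @pytest.mark.parametrize("kind", ["square", "diamond"])
    def test_duality_erosion_vs_dilation(self, kind):
        # the complement extends beyond the array, so dilate it on a
        # True-padded copy to realize the infinite-domain identity
        m = rand_mask((16, 16, 16), 1)
        se = StructuringElement(kind, 1, ndim=3)
        comp_dil = morph(np.pad(~m, 1, constant_values=True), "dilate", se)
        assert np.array_equal(morph(m, "erode", se),
                              ~comp_dil[1:-1, 1:-1, 1:-1])

    def test_opening_anti_extensive_idempotent(self):
        m = rand_mask((20, 20), 2)
        se = StructuringElement("diamond", 1)
        opened = morph(m, "open", se)
        assert not (opened & ~m).any()
        assert np.array_equal(morph(opened, "open", se), opened)

    def test_closing_extensive_idempotent(self):
        # pad so the bounded-window closing equals the infinite-domain one,
        # which is the operation with the extensivity guarantee
        m = np.pad(rand_mask((20, 20), 3), 3, constant_values=False)
        se = StructuringElement("square", 1)
        closed = morph(m, "close", se)
        assert not (m & ~closed).any()
        assert np.array_equal(morph(closed, "close", se), closed)


class TestFillHoles:
    def test_ring_becomes_disk(self):
        m = np.zeros((9, 9), bool)
        m[2:7, 2:7] = True
        m[3:6, 3:6] = False
        filled = fill_holes_2d(m)
        assert filled[4, 4] and filled.sum() == 25

    def test_mask_without_holes_unchanged(self):
        m = rand_mask((9, 9), 4, p=0.2)
        m[0] = m[-1] = m[:, 0] = m[:, -1] = False
        open_m = m & False
        open_m[2:4, 2:4] = True
        assert np.array_equal(fill_holes_2d(open_m), open_m)

    def test_nested_rings_fully_filled(self):
        m = np.zeros((13, 13), bool)
        m[1:12, 1:12] = True
        m[2:11, 2:11] = False
        m[4:9, 4:9] = True
        m[5:8, 5:8] = False
        filled = fill_holes_2d(m)
        # flood-fill-from-border oracle
        from scipy import ndimage
        lab, _ = ndimage.label(~m)
        border_labels = set(np.unique(np.concatenate(
            [lab[0], lab[-1], lab[:, 0], lab[:, -1]]))) - {0}
        expected = m | ~np.isin(lab, sorted(border_labels))
        assert np.array_equal(filled, expected)
        assert filled[6, 6]


class TestComponents:
    def test_two_separate_pixels(self):
        m = np.zeros((5, 5), bool)
        m[0, 0] = m[4, 4] = True
        _, sizes = connected_components(m)
        assert len(sizes) == 2

    def test_diagonal_connectivity_modes(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[2, 2] = True
        assert len(connected_components(m, "face")[1]) == 2
        assert len(connected_components(m, "full")[1]) == 1

    def test_empty_mask(self):
        _, sizes = connected_components(np.zeros((3, 3), bool))
        assert len(sizes) == 0

    def test_keep_largest_by_size(self):
        m = np.zeros((5, 15), bool)
        m[1:2, 0:5] = True    # size 5
        m[3:4, 0:3] = True    # size 3
        m[3, 10] = True       # size 1
        out = keep_largest(m, 2)
        assert out.sum() == 8 and not out[3, 10]

    def test_keep_largest_k_exceeds_count(self):
        m = np.zeros((4, 4), bool)
        m[0, 0] = True
        assert np.array_equal(keep_largest(m, 5), m)

    def test_keep_largest_empty(self):
        m = np.zeros((4, 4), bool)
        assert not keep_largest(m, 1).any()


class TestGradientMagnitude:
    def test_constant_volume_zero(self):
        g = gradient_magnitude(np.full((6, 6, 6), 7.0))
        assert np.allclose(g, 0.0)

    def test_step_edge_peak_on_plane_and_symmetric(self):
        v = np.zeros((7, 7, 7))
        v[3:, :, :] = 100.0
        g = gradient_magnitude(v)
        profile = g[:, 3, 3]
        assert np.argmax(profile) in (2, 3)
        assert profile[1] == pytest.approx(profile[4], rel=1e-9) or \
               profile[2] == pytest.approx(profile[3], rel=1e-9)

    def test_rotation_equivariance_for_axis_swaps(self):
        rng = np.random.default_rng(5)
        v = rng.random((8, 8, 8))
        g = gradient_magnitude(v)
        g_rot = gradient_magnitude(np.transpose(v, (1, 0, 2)))
        assert np.allclose(np.transpose(g, (1, 0, 2)), g_rot)

    def test_offset_invariance_and_gain_linearity(self):
        rng = np.random.default_rng(6)
        v = rng.random((8, 8, 8)) * 50
        g = gradient_magnitude(v)
        assert np.allclose(gradient_magnitude(v + 123.0), g)
        assert np.allclose(gradient_magnitude(v * 3.0), g * 3.0)

    def test_too_small_volume_raises(self):
        with pytest.raises(ValueError):
            gradient_magnitude(np.zeros((2, 5, 5)))


class TestMaxEntropyThreshold:
    def test_separates_two_delta_modes(self):
        hist = np.zeros(64)
        hist[10] = 500
        hist[50] = 400
        t = max_entropy_threshold(hist)
        assert 10 <= t < 50

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            hist = rng.integers(0, 50, size=rng.integers(8, 64))
            if np.count_nonzero(hist) < 2:
                continue
            assert max_entropy_threshold(hist) == kapur_oracle(hist)

    def test_count_scale_invariance(self):
        rng = np.random.default_rng(8)
        hist = rng.integers(1, 30, size=40)
        assert max_entropy_threshold(hist) == max_entropy_threshold(hist * 7)

    def test_degenerate_histogram_raises(self):
        hist = np.zeros(10)
        hist[3] = 5
        with pytest.raises(ValueError):
            max_entropy_threshold(hist)


class TestSmoothHistogram:
    def test_box_one_is_identity(self):
        h = np.arange(10, dtype=float)
        assert np.array_equal(smooth_histogram(h, 1), h)

    def test_impulse_spreads_to_plateau(self):
        h = np.zeros(31)
        h[15] = 1.0
        s = smooth_histogram(h, 11)
        assert np.allclose(s[10:21], 1 / 11)
        assert np.allclose(s[:10], 0) and np.allclose(s[21:], 0)

    def test_constant_histogram_unchanged(self):
        h = np.full(20, 3.0)
        assert np.allclose(smooth_histogram(h, 5), h)

    def test_even_box_raises(self):
        with pytest.raises(ValueError):
            smooth_histogram(np.ones(5), 4)


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 2**31 - 1))
def test_morphological_duality_random_volumes(seed):
    m = np.random.default_rng(seed).random((8, 8, 8)) < 0.5
    se = StructuringElement("diamond", 1, ndim=3)
    comp_dil = morph(np.pad(~m, 1, constant_values=True), "dilate", se)
    assert np.array_equal(morph(m, "erode", se), ~comp_dil[1:-1, 1:-1, 1:-1])
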