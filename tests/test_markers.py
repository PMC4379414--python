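"""Marker construction: growth paths, central pixels, carpal region,
finalization and assembly."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from wristseg.hand_mask import build_hand_mask, select_mask_threshold
from wristseg.labels import BONE_IDS, CARPALS
from wristseg.markers import (assemble_markers, carpal_region, central_pixel,
                              finalize_carpal_markers, grow_marker,
                              match_components, _support_line)
from conftest import grow_oracle


class TestGrowMarker:
    def test_uniform_tube_gives_straight_column(self):
        vol = np.zeros((5, 5, 16))
        vol[2, 2, :] = 100.0  # bright 1-voxel tube along z
        marker = grow_marker(vol, (2, 2, 2), depth_slices=10, direction="proximal")
        assert marker.sum() == 11
        assert all(marker[2, 2, z] for z in range(2, 13))

    def test_follows_bright_curved_channel(self):
        vol = np.zeros((20, 20, 20))
        xs = [5 + int(round(4 * np.sin(z / 4))) for z in range(20)]
        for z, x in enumerate(xs):
            vol[x, 10, z] = 200.0
        marker = grow_marker(vol, (xs[4], 10, 4), depth_slices=10)
        on_channel = sum(vol[tuple(v)] > 0 for v in np.argwhere(marker))
        # path voxels may step off the channel only to bridge neighbouring
        # channel voxels that are not face-adjacent
        assert on_channel >= marker.sum() - 10
        assert marker.sum() >= 11

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_best_first_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vol = rng.integers(0, 5, (8, 8, 14)).astype(float)  # many ties
        start = (4, 4, 2)
        got = grow_marker(vol, start, depth_slices=8, direction="proximal")
        want = grow_oracle(vol, start, 8, "proximal")
        assert np.array_equal(got, want)

    def test_distal_direction_restriction(self):
        vol = np.random.default_rng(1).random((6, 6, 20))
        marker = grow_marker(vol, (3, 3, 15), depth_slices=10, direction="distal")
        zs = np.nonzero(marker)[2]
        assert zs.max() <= 15 and zs.min() == 5

    def test_truncation_at_volume_edge_warns(self):
        vol = np.ones((4, 4, 6))
        with pytest.warns(UserWarning, match="truncated"):
            marker = grow_marker(vol, (2, 2, 2), depth_slices=10)
        assert marker.any()


class TestCentralPixel:
    def test_square_center(self):
        m = np.zeros((9, 9), bool)
        m[2:7, 2:7] = True
        assert central_pixel(m) == (4, 4)

    def test_l_shape_matches_distance_transform_argmax(self):
        m = np.zeros((12, 12), bool)
        m[2:10, 2:5] = True
        m[7:10, 2:10] = True
        px = central_pixel(m)
        dist = ndimage.distance_transform_cdt(np.pad(m, 1), metric="taxicab")[1:-1, 1:-1]
        assert dist[px] == dist.max()
        # lexicographic tie-break: no earlier pixel attains the maximum
        flat = np.flatnonzero(dist == dist.max())
        assert np.ravel_multi_index(px, m.shape) == flat[0]

    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[3, 1] = True
        assert central_pixel(m) == (3, 1)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            central_pixel(np.zeros((3, 3), bool))


class TestSupportLine:
    def test_tangent_keeps_both_ellipsoids_and_reference(self):
        a = np.zeros((30, 6, 30), bool)
        b = np.zeros((30, 6, 30), bool)
        xx, yy, zz = np.meshgrid(*(np.arange(s) for s in a.shape), indexing="ij")
        a[((xx - 22) / 4.0) ** 2 + ((yy - 3) / 2.0) ** 2 + ((zz - 24) / 4.0) ** 2 <= 1] = True
        b[((xx - 26) / 3.0) ** 2 + ((yy - 3) / 2.0) ** 2 + ((zz - 6) / 4.0) ** 2 <= 1] = True
        ref = (10.0, 15.0)
        line = _support_line(a, b, ref)
        assert line is not None
        la, lb, lc = line
        assert la * ref[0] + lb * ref[1] + lc > 0
        for body in (a, b):
            pts = np.argwhere(body.any(axis=1))
            side = la * pts[:, 0] + lb * pts[:, 1] + lc
            assert (side >= -1e-6).all()          # bodies on the kept side
            assert np.isclose(side.min(), 0, atol=1.0)  # and tangent to it


class TestCarpalRegion:
    def test_phantom_region_contains_carpals_and_excludes_stages(self, small_phantom):
        spec, vol, labels = small_phantom
        ru = np.where(np.isin(labels, [1, 2]), labels, 0)
        mc = np.where(np.isin(labels, [3, 4, 5, 6, 7]), labels, 0)
        mask = build_hand_mask(vol, select_mask_threshold(vol))
        region = carpal_region(ru, mc, mask)
        for name in CARPALS:
            body = labels == BONE_IDS[name]
            assert (body & region).sum() == body.sum(), name
        assert not (region & (ru > 0)).any()
        assert not (region & (mc > 0)).any()
        assert not (region & ~mask).any()

    def test_empty_stage_raises(self):
        z = np.zeros((8, 8, 8), np.int32)
        with pytest.raises(ValueError):
            carpal_region(z, z, np.ones((8, 8, 8), bool))


class TestFinalizeCarpalMarkers:
    def test_dark_candidate_voxels_removed(self):
        vol = np.full((16, 16, 6), 100, np.uint16)
        vol[2:6, 2:6, 1:5] = 2000
        cand = np.zeros(vol.shape, bool)
        cand[2:6, 2:6, 1:5] = True   # bright: survives
        cand[9:12, 9:12, 1:5] = True  # dark: must be removed
        comps = finalize_carpal_markers(cand, vol, th_me=1000, buffer=200,
                                        n_components=1)
        assert len(comps) == 1
        assert not comps[0][9:12, 9:12].any()

    def test_keeps_exactly_requested_count(self):
        # components spaced widely enough that the slicewise closing cannot
        # bridge them
        vol = np.full((62, 12, 6), 2000, np.uint16)
        cand = np.zeros(vol.shape, bool)
        for i in range(12):
            cand[5 * i : 5 * i + 2, 3 : 5 + (i % 3), 2:4] = True
        comps = finalize_carpal_markers(cand, vol, th_me=1000, buffer=200,
                                        n_components=8)
        assert len(comps) == 8
        sizes = [c.sum() for c in comps]
        assert sizes == sorted(sizes, reverse=True)

    def test_too_few_components_raises_with_count(self):
        vol = np.full((10, 10, 4), 2000, np.uint16)
        cand = np.zeros(vol.shape, bool)
        cand[2:4, 2:4, 1:3] = True
        with pytest.raises(ValueError, match="1"):
            finalize_carpal_markers(cand, vol, th_me=1000, buffer=200,
                                    n_components=8)


class TestAssembleMarkers:
    def _markers(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[1, 1, 1] = b[4, 4, 4] = True
        return a, b

    def test_disjoint_markers_unchanged(self):
        a, b = self._markers()
        bg = np.zeros_like(a)
        bg[0, :, :] = True
        ms = assemble_markers({"R": a, "U": b}, bg)
        assert np.array_equal(ms.markers["R"], a)
        assert np.array_equal(ms.background, bg)
        assert ms.names == ["R", "U"]

    def test_background_overlap_trimmed_with_warning(self):
        a, b = self._markers()
        bg = np.ones_like(a)
        with pytest.warns(UserWarning, match="trimmed"):
            ms = assemble_markers({"R": a, "U": b}, bg)
        assert not (ms.background & (a | b)).any()

    def test_object_overlap_raises(self):
        a, _ = self._markers()
        with pytest.raises(ValueError, match="overlaps"):
            assemble_markers({"R": a, "U": a}, np.zeros_like(a))

    def test_empty_marker_names_bone(self):
        a, _ = self._markers()
        with pytest.raises(ValueError, match="U"):
            assemble_markers({"R": a, "U": np.zeros_like(a)}, np.zeros_like(a))

    def test_labelmap_round_trip(self):
        a, b = self._markers()
        bg = np.zeros_like(a)
        bg[0] = True
        ms = assemble_markers({"R": a, "U": b}, bg)
        lab = ms.to_labelmap()
        assert lab[1, 1, 1] == 1 and lab[4, 4, 4] == 2 and lab[0, 0, 0] == 3
        assert ms.label_names()[3] == "background"


class TestMatchComponents:
    def test_optimal_assignment_by_overlap(self):
        c1 = np.zeros((10, 10), bool)
        c2 = np.zeros((10, 10), bool)
        c1[1:4, 1:4] = True
        c2[6:9, 6:9] = True
        refs = {"X": np.zeros((10, 10)), "Y": np.zeros((10, 10))}
        refs["X"][6:9, 6:9] = 255.0
        refs["Y"][1:4, 1:4] = 255.0
        named = match_components([c1, c2], refs)
        assert named["Y"] is c1 and named["X"] is c2

    def test_count_mismatch_raises(self):
        with pytest.raises(ValueError):
            match_components([np.zeros((4, 4), bool)],
                             {"X": np.zeros((4, 4)), "Y": np.zeros((4, 4))})
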