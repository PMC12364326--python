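import numpy as np
import pytest
from hypothesis import given, strategies as st
from skimage.measure import block_reduce

from heeseggan.errors import ConfigurationError, EmptyMaskError, ShapeError
from heeseggan.preprocessing import (WindowSpec, build_pyramid,
                                     composite_from_volume, encode_pseudocolor,
                                     extract_edge_map, extract_roi,
                                     mask_moment_center, window_hu)


class TestWindowHU:
    def test_level_maps_to_half(self):
        assert window_hu(np.array([[-600.0]])) == pytest.approx(0.5)

    def test_below_floor_clips_to_zero(self):
        assert window_hu(np.array([[-2000.0]])) == pytest.approx(0.0)

    def test_ceiling_maps_to_one(self):
        assert window_hu(np.array([[0.0]])) == pytest.approx(1.0)

    @given(st.lists(st.floats(-3000, 3000), min_size=2, max_size=20))
    def test_monotone_nondecreasing(self, values):
        hu = np.sort(np.array(values))
        out = window_hu(hu.reshape(1, -1))[0]
        assert (np.diff(out) >= 0).all()

    def test_bad_width_rejected(self):
        with pytest.raises(ConfigurationError):
            WindowSpec(level=-600, width=0)

    def test_literal_interpretation_selectable(self):
        # window over [-600, 1200] instead of the lung default
        spec = WindowSpec(level=300, width=1800)
        assert spec.floor == pytest.approx(-600)
        assert spec.ceiling == pytest.approx(1200)


class TestMomentCenter:
    def test_single_pixel(self):
        mask = np.zeros((32, 32))
        mask[10, 20] = 1
        assert mask_moment_center(mask) == (10.0, 20.0)

    def test_filled_square_symmetry(self):
        mask = np.zeros((32, 32))
        mask[8:12, 8:12] = 1
        assert mask_moment_center(mask) == (9.5, 9.5)

    def test_l_shape_brute_force(self):
        # oracle: average of coordinates {(0,0),(0,1),(1,0)}
        mask = np.zeros((4, 4))
        mask[0, 0] = mask[0, 1] = mask[1, 0] = 1
        r, c = mask_moment_center(mask)
        assert r == pytest.approx(1 / 3)
        assert c == pytest.approx(1 / 3)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            mask_moment_center(np.zeros((8, 8)))


class TestExtractROI:
    def test_central_crop_no_padding(self, rng):
        grid = rng.random((512, 512))
        out = extract_roi(grid, (255.5, 255.5), 128)
        np.testing.assert_array_equal(out, grid[192:320, 192:320])

    def test_corner_padded(self, rng):
        grid = rng.random((256, 256))
        out = extract_roi(grid, (0.0, 0.0), 128)
        assert (out[:64, :] == 0).all() and (out[:, :64] == 0).all()
        np.testing.assert_array_equal(out[64:, 64:], grid[:64, :64])

    def test_centroid_self_consistency(self, rng):
        # oracle: re-centroid of the cropped mask sits at the ROI centre
        for seed in range(5):
            r = np.random.default_rng(seed)
            mask = np.zeros((256, 256))
            cy, cx = r.uniform(60, 196, 2)
            yy, xx = np.mgrid[0:256, 0:256]
            mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= 81] = 1
            crop = extract_roi(mask, mask_moment_center(mask), 128)
            rr, cc = mask_moment_center(crop)
            assert abs(rr - 63.5) <= 1.0 and abs(cc - 63.5) <= 1.0

    def test_bad_size_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            extract_roi(rng.random((64, 64)), (32, 32), size=15)


class TestEncodePseudocolor:
    def test_identical_slices_identical_channels(self, rng):
        sl = rng.random((64, 64))
        vol = np.stack([sl, sl, sl])
        img = encode_pseudocolor(vol, 1, (31.5, 31.5), 32)
        np.testing.assert_array_equal(img.pixels[..., 0], img.pixels[..., 1])
        np.testing.assert_array_equal(img.pixels[..., 1], img.pixels[..., 2])

    def test_single_slice_structure_green_only(self):
        vol = np.zeros((3, 64, 64))
        vol[1, 30:34, 30:34] = 1.0  # structure on the current slice only
        img = encode_pseudocolor(vol, 1, (32.0, 32.0), 32)
        assert img.pixels[..., 1].sum() > 0
        assert img.pixels[..., 0].sum() == 0
        assert img.pixels[..., 2].sum() == 0

    def test_vessel_colored_on_all_channels(self, phantom_sample):
        s = phantom_sample
        z = s.nodule_center[0]
        img = encode_pseudocolor(
            window_hu(s.volume), z, s.nodule_center[1:], 64)
        vessel_crop = extract_roi(s.vessel_volume[z], s.nodule_center[1:], 64)
        track = vessel_crop.astype(bool)
        assert track.any()
        assert (img.pixels[track].min(axis=1) > 0).all()

    def test_edge_replication_at_volume_ends(self, rng):
        vol = rng.random((3, 64, 64))
        first = encode_pseudocolor(vol, 0, (31.5, 31.5), 32)
        np.testing.assert_array_equal(first.pixels[..., 0], first.pixels[..., 1])
        last = encode_pseudocolor(vol, 2, (31.5, 31.5), 32)
        np.testing.assert_array_equal(last.pixels[..., 1], last.pixels[..., 2])

    def test_crop_window_commutes(self, phantom_sample):
        # holds wherever the crop stays inside the volume (padding is exempt:
        # zero-padding is in windowed units, not HU)
        s = phantom_sample
        z, center = s.nodule_center[0], (32.0, 32.0)
        a = encode_pseudocolor(window_hu(s.volume), z, center, 16).pixels
        cropped = np.stack([extract_roi(s.volume[i], center, 16)
                            for i in (z - 1, z, z + 1)], axis=-1)
        np.testing.assert_allclose(a, window_hu(cropped), atol=1e-12)


class TestEdgeMap:
    def test_square_perimeter(self):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[4:9, 4:9] = 1
        assert extract_edge_map(mask).sum() == 16

    def test_single_pixel_is_its_own_edge(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[3, 3] = 1
        np.testing.assert_array_equal(extract_edge_map(mask), mask)

    def test_disc_edge_count_near_circumference(self):
        yy, xx = np.mgrid[0:64, 0:64]
        mask = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 64).astype(np.uint8)
        count = extract_edge_map(mask).sum()
        assert abs(count - 2 * np.pi * 8) <= 0.20 * 2 * np.pi * 8

    def test_empty_mask_empty_edges(self):
        assert extract_edge_map(np.zeros((8, 8))).sum() == 0

    def test_canny_variant_runs(self):
        yy, xx = np.mgrid[0:64, 0:64]
        mask = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 100).astype(np.uint8)
        edge = extract_edge_map(mask, method="canny")
        assert edge.sum() > 0 and set(np.unique(edge)) <= {0, 1}


class TestPyramid:
    def test_all_zero(self):
        pyr = build_pyramid(np.zeros((128, 128)), kind="mask")
        assert all(lv.sum() == 0 for lv in pyr.levels)

    def test_single_pixel_survives_every_level(self):
        mask = np.zeros((128, 128))
        mask[37, 101] = 1
        pyr = build_pyramid(mask, kind="mask")
        assert [lv.sum() for lv in pyr.levels] == [1, 1, 1, 1]

    def test_disc_level4_matches_block_max_oracle(self):
        yy, xx = np.mgrid[0:128, 0:128]
        mask = ((yy - 64) ** 2 + (xx - 64) ** 2 <= 256).astype(np.uint8)
        pyr = build_pyramid(mask, kind="mask")
        oracle = block_reduce(mask, (8, 8), np.max)
        np.testing.assert_array_equal(pyr.levels[3], oracle)
        assert pyr.levels[3].shape == (16, 16)

    def test_level_sizes_and_binary(self, rng):
        mask = (rng.random((128, 128)) > 0.9).astype(np.uint8)
        pyr = build_pyramid(mask, kind="edge")
        assert [lv.shape[0] for lv in pyr.levels] == [128, 64, 32, 16]
        np.testing.assert_array_equal(pyr.levels[0], mask)
        for lv in pyr.levels:
            assert set(np.unique(lv)) <= {0, 1}

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ShapeError):
            build_pyramid(np.zeros((60, 60)))


def test_full_pipeline_shapes(phantom_sample):
    image, mask, y_d, y_g = composite_from_volume(
        phantom_sample.volume, phantom_sample.mask_volume, size=64)
    assert image.pixels.shape == (64, 64, 3)
    assert image.pixels.min() >= 0 and image.pixels.max() <= 1
    assert mask.shape == (64, 64) and mask.sum() > 0
    assert y_d.kind == "mask" and y_g.kind == "edge"
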