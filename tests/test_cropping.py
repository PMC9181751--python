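import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from choroidnet import (BScanImage, CropConfig, candidate_offsets, crop_bscan,
                        extract_pixels, place_window)
from choroidnet.cropping import PatchGeometry
from choroidnet.errors import GeometryError


def brute_force_row_start(pixels, col_start, col_end, patch_height, stride):
    """Independent exhaustive argmax over the candidate offsets."""
    plane = pixels.sum(axis=2) if pixels.ndim == 3 else pixels
    offsets = candidate_offsets(plane.shape[0], patch_height, stride)
    sums = [plane[o:o + patch_height, col_start:col_end].sum() for o in offsets]
    return int(offsets[int(np.argmax(sums))])


class TestCandidateOffsets:
    def test_terminal_offset_appended(self):
        offsets = candidate_offsets(596, 200, 10)
        assert offsets[0] == 0 and offsets[-1] == 396
        assert list(offsets[:-1]) == list(range(0, 391, 10))

    def test_exact_tiling_no_append(self):
        assert list(candidate_offsets(100, 50, 50)) == [0, 50]

    def test_tall_patch_two_offsets(self):
        assert list(candidate_offsets(100, 99, 10)) == [0, 1]

    def test_strictly_increasing(self):
        offsets = candidate_offsets(337, 41, 7)
        assert np.all(np.diff(offsets) > 0)
        assert offsets[-1] == 337 - 41

    def test_patch_taller_than_image_rejected(self):
        with pytest.raises(GeometryError):
            candidate_offsets(100, 100, 10)


class TestPlaceWindow:
    def test_bright_band_attracts_window(self):
        pixels = np.zeros((596, 200))
        pixels[300:380, :] = 1.0
        image = BScanImage(pixels=pixels)
        geom = place_window(image, 0, CropConfig(k_segments=1, patch_height=200))
        # any offset in [180, 300] covers the whole band; ties go to the smallest
        assert 180 <= geom.row_start <= 300
        assert geom.row_start == brute_force_row_start(pixels, 0, 200, 200, 10)

    def test_uniform_image_ties_to_smallest_offset(self):
        image = BScanImage(pixels=np.full((100, 40), 0.5))
        geom = place_window(image, 0, CropConfig(k_segments=1, patch_height=30))
        assert geom.row_start == 0

    def test_matches_brute_force_on_random_images(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            h = int(rng.integers(20, 80))
            w = int(rng.integers(4, 40)) * 2
            n = int(rng.integers(5, h - 1))
            stride = int(rng.integers(1, 12))
            pixels = rng.uniform(size=(h, w))
            image = BScanImage(pixels=pixels)
            config = CropConfig(k_segments=2, patch_height=n, vertical_stride=stride)
            for k in (0, 1):
                geom = place_window(image, k, config)
                expected = brute_force_row_start(pixels, geom.col_start,
                                                 geom.col_end, n, stride)
                assert geom.row_start == expected

    def test_translation_covariance_on_zero_background(self):
        rng = np.random.default_rng(1)
        blob = rng.uniform(0.5, 1.0, size=(20, 30))
        for shift in (0, 10, 20):
            pixels = np.zeros((120, 30))
            pixels[40 + shift:60 + shift, :] = blob
            geom = place_window(BScanImage(pixels=pixels), 0,
                                CropConfig(k_segments=1, patch_height=20))
            assert geom.row_start == 40 + shift

    def test_channels_are_summed(self):
        pixels = np.zeros((100, 20, 3))
        pixels[60:80, :, 2] = 1.0  # signal lives in one channel only
        geom = place_window(BScanImage(pixels=pixels), 0,
                            CropConfig(k_segments=1, patch_height=20))
        assert geom.row_start == 60


class TestCropBScan:
    @pytest.mark.parametrize("k,patch_height,expected", [(16, 50, 16), (4, 200, 4)])
    def test_patch_counts_for_800_wide_scan(self, k, patch_height, expected):
        image = BScanImage(pixels=np.random.default_rng(0).uniform(size=(596, 800)))
        geoms = crop_bscan(image, CropConfig(k_segments=k, patch_height=patch_height))
        assert len(geoms) == expected
        assert all(g.width == 800 // k for g in geoms)

    def test_columns_partition_width(self):
        image = BScanImage(pixels=np.random.default_rng(1).uniform(size=(100, 60)))
        geoms = crop_bscan(image, CropConfig(k_segments=3, patch_height=40))
        covered = sorted((g.col_start, g.col_end) for g in geoms)
        assert covered[0][0] == 0 and covered[-1][1] == 60
        for (_, e), (s, _) in zip(covered, covered[1:]):
            assert e == s

    def test_single_patch_spans_width(self):
        image = BScanImage(pixels=np.zeros((50, 30)))
        geoms = crop_bscan(image, CropConfig(k_segments=1, patch_height=20))
        assert len(geoms) == 1
        assert (geoms[0].col_start, geoms[0].col_end) == (0, 30)

    def test_indivisible_width_rejected(self):
        image = BScanImage(pixels=np.zeros((50, 31)))
        with pytest.raises(GeometryError, match="divisible"):
            crop_bscan(image, CropConfig(k_segments=2, patch_height=20))


class TestExtractPixels:
    def test_full_image_identity(self):
        pixels = np.random.default_rng(2).uniform(size=(10, 10))
        image = BScanImage(pixels=pixels)
        geom = PatchGeometry(col_start=0, col_end=10, row_start=0, row_end=10,
                             segment_index=0)
        assert np.array_equal(extract_pixels(image, geom), pixels)

    def test_literal_subblock(self):
        pixels = (np.arange(100, dtype=float).reshape(10, 10)) / 100.0
        image = BScanImage(pixels=pixels)
        geom = PatchGeometry(col_start=3, col_end=5, row_start=2, row_end=4,
                             segment_index=0)
        assert np.array_equal(extract_pixels(image, geom), pixels[2:4, 3:5])

    def test_adjacent_patches_reconstruct_source(self):
        pixels = np.random.default_rng(3).uniform(size=(30, 20))
        image = BScanImage(pixels=pixels)
        left = PatchGeometry(0, 10, 5, 25, 0)
        right = PatchGeometry(10, 20, 5, 25, 1)
        joined = np.concatenate([extract_pixels(image, left),
                                 extract_pixels(image, right)], axis=1)
        assert np.array_equal(joined, pixels[5:25, :])

    def test_out_of_bounds_rejected(self):
        image = BScanImage(pixels=np.zeros((10, 10)))
        with pytest.raises(GeometryError):
            extract_pixels(image, PatchGeometry(0, 10, 5, 15, 0))

    def test_returns_copy(self):
        image = BScanImage(pixels=np.zeros((10, 10)))
        patch = extract_pixels(image, PatchGeometry(0, 5, 0, 5, 0))
        patch[...] = 1.0
        assert image.pixels.max() == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(20, 60), st.integers(2, 6), st.integers(1, 15), st.integers(0, 2**31 - 1))
def test_place_window_equals_brute_force_property(height, k, stride, seed):
    """Sliding-window argmax equals exhaustive search for arbitrary images."""
    rng = np.random.default_rng(seed)
    width = k * int(rng.integers(2, 10))
    n = int(rng.integers(2, height - 1))
    pixels = rng.uniform(size=(height, width))
    image = BScanImage(pixels=pixels)
    config = CropConfig(k_segments=k, patch_height=n, vertical_stride=stride)
    for geom in crop_bscan(image, config):
        expected = brute_force_row_start(pixels, geom.col_start, geom.col_end, n, stride)
        assert geom.row_start == expected
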