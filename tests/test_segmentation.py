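"""Segmentation stage: filters against brute-force oracles, Otsu, size rule."""

import numpy as np
import pytest

from larvatrack.segmentation import (
    DetectionSet,
    Region,
    SegmentationParams,
    connected_components,
    gray_erosion,
    median_filter_3x3,
    otsu_threshold,
    segment_frame,
    size_filter,
)


# --- naive oracles -----------------------------------------------------------

def naive_median_3x3(image):
    h, w = image.shape
    padded = np.pad(image, 1, mode="edge")
    out = np.empty_like(image)
    for r in range(h):
        for c in range(w):
            out[r, c] = np.median(padded[r : r + 3, c : c + 3])
    return out


def naive_erosion_3x3(image):
    h, w = image.shape
    padded = np.pad(image, 1, mode="edge")
    out = np.empty_like(image)
    for r in range(h):
        for c in range(w):
            out[r, c] = padded[r : r + 3, c : c + 3].min()
    return out


def naive_otsu(values):
    hist = np.bincount(np.asarray(values).ravel(), minlength=256)
    best_t, best_var = 0, -1.0
    levels = np.arange(256)
    for t in range(255):
        w0 = hist[: t + 1].sum()
        w1 = hist[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def flood_fill_components(binary):
    """BFS flood fill with 8-connectivity; returns a set of frozen pixel sets."""
    binary = np.asarray(binary, bool)
    seen = np.zeros_like(binary)
    comps = []
    h, w = binary.shape
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and binary[yy, xx] and not seen[yy, xx]:
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                comps.append(frozenset(comp))
    return set(comps)


# --- filters -----------------------------------------------------------------

class TestFilters:
    def test_constant_images_unchanged(self):
        img = np.full((10, 10), 77, dtype=np.uint8)
        np.testing.assert_array_equal(median_filter_3x3(img), img)
        np.testing.assert_array_equal(gray_erosion(img), img)

    def test_median_removes_isolated_bright_pixel(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[4, 4] = 255
        assert median_filter_3x3(img)[4, 4] == 0

    def test_erosion_suppresses_one_pixel_wide_bright_line(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[4, :] = 200
        assert (gray_erosion(img) == 0).all()

    @pytest.mark.parametrize("trial", range(5))
    def test_median_matches_naive_oracle_on_random_images(self, rng, trial):
        img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        np.testing.assert_array_equal(median_filter_3x3(img), naive_median_3x3(img))

    @pytest.mark.parametrize("trial", range(5))
    def test_erosion_matches_naive_oracle_on_random_images(self, rng, trial):
        img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        np.testing.assert_array_equal(gray_erosion(img), naive_erosion_3x3(img))


class TestOtsu:
    def test_perfectly_bimodal_split(self):
        img = np.concatenate([np.zeros(50, np.uint8), np.full(50, 255, np.uint8)])
        t = otsu_threshold(img)
        assert 0 <= t < 255
        assert (img <= t).sum() == 50

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_search_on_random_histograms(self, rng, trial):
        img = rng.integers(0, 256, size=2000, dtype=np.uint8)
        assert otsu_threshold(img) == naive_otsu(img)

    def test_two_gaussian_modes_split_between_them(self, rng):
        values = np.concatenate([
            rng.normal(60, 5, 500), rng.normal(180, 5, 500)
        ]).clip(0, 255).astype(np.uint8)
        assert 60 < otsu_threshold(values) < 180

    def test_agrees_with_skimage_on_uint8_data(self, rng):
        from skimage.filters import threshold_otsu

        img = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        ours = otsu_threshold(img)
        theirs = threshold_otsu(img)
        # conventions differ by at most the bin boundary
        assert abs(ours - theirs) <= 1

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((5, 5), 9, dtype=np.uint8))


class TestConnectedComponents:
    def test_single_square_block(self):
        mask = np.zeros((20, 20), bool)
        mask[10:13, 10:13] = True
        regions = connected_components(mask)
        assert len(regions) == 1
        r = regions[0]
        assert r.area == 9
        assert r.centroid == (11.0, 11.0)
        assert r.bbox == (10, 10, 12, 12)

    def test_diagonal_pixels_join_under_8_connectivity(self):
        mask = np.zeros((5, 5), bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(connected_components(mask, connectivity=8)) == 1
        assert len(connected_components(mask, connectivity=4)) == 2

    @pytest.mark.parametrize("trial", range(5))
    def test_partition_matches_flood_fill_oracle(self, rng, trial):
        mask = rng.random((40, 40)) < 0.3
        regions = connected_components(mask)
        ours = {frozenset(map(tuple, r.coords)) for r in regions}
        assert ours == flood_fill_components(mask)

    def test_empty_mask_gives_no_regions(self):
        assert connected_components(np.zeros((8, 8), bool)) == []


def _region(area):
    coords = np.zeros((area, 2), dtype=int)
    return Region(label=1, area=area, centroid=(0.0, 0.0), bbox=(0, 0, 1, 1), coords=coords)


class TestSizeFilter:
    def test_removes_region_below_20_percent_of_mean(self):
        regions = [_region(100), _region(100), _region(10)]
        kept = size_filter(regions, 0.2)  # mean 70, cutoff 14
        assert sorted(r.area for r in kept) == [100, 100]

    def test_equal_areas_all_kept(self):
        kept = size_filter([_region(50)] * 4, 0.2)
        assert len(kept) == 4

    def test_borderline_pair_both_kept(self):
        kept = size_filter([_region(50), _region(9)], 0.2)  # mean 29.5, cutoff 5.9
        assert sorted(r.area for r in kept) == [9, 50]

    def test_empty_input_passes_through(self):
        assert size_filter([], 0.2) == []

    def test_output_is_subset_of_input(self, rng):
        regions = [_region(int(a)) for a in rng.integers(1, 200, 30)]
        kept = size_filter(regions, 0.2)
        ids = {id(r) for r in regions}
        assert all(id(r) in ids for r in kept)


class TestSegmentFrame:
    def test_empty_mask_gives_empty_detections(self):
        frame = np.full((32, 32), 200, dtype=np.uint8)
        dets = segment_frame(frame, np.zeros((32, 32), bool))
        assert len(dets) == 0

    def test_larvae_survive_and_noise_dots_are_removed(self, rng):
        """Three dark bodies plus twenty 1-px noise specks → 3 regions."""
        frame = np.full((96, 96), 200, dtype=np.uint8)
        mask = np.zeros((96, 96), bool)
        centres = [(20, 20), (20, 70), (70, 45)]
        for cy, cx in centres:
            frame[cy - 2 : cy + 3, cx - 5 : cx + 6] = 70
            mask[cy - 2 : cy + 3, cx - 5 : cx + 6] = True
        for _ in range(20):
            y, x = rng.integers(5, 90, 2)
            if not mask[y - 2 : y + 3, x - 2 : x + 3].any():
                frame[y, x] = 60
                mask[y, x] = True
        dets = segment_frame(frame, mask)
        assert len(dets) == 3
        got = sorted((round(c[1]), round(c[0])) for c in (r.centroid for r in dets.regions))
        assert got == sorted(centres)

    def test_small_ripple_blob_is_size_filtered(self):
        """A blob at 15 % of mean body area is removed by the 20 % rule."""
        frame = np.full((64, 64), 200, dtype=np.uint8)
        mask = np.zeros((64, 64), bool)
        for cy, cx in [(16, 16), (16, 48)]:
            frame[cy - 3 : cy + 4, cx - 5 : cx + 6] = 70  # 7×11 = 77 px bodies
            mask[cy - 3 : cy + 4, cx - 5 : cx + 6] = True
        frame[47:50, 30:33] = 75  # 9 px ripple ≈ 15 % of the eroded body area
        mask[47:50, 30:33] = True
        dets = segment_frame(frame, mask)
        assert len(dets) == 2
        assert all(r.centroid[1] < 40 for r in dets.regions)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segment_frame(np.zeros((4, 4)), np.zeros((5, 5), bool))
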