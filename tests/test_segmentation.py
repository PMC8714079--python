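"""Thresholding against exhaustive-search oracles, filters, and mask geometry."""

import math

import numpy as np
import pytest
from skimage.filters import threshold_otsu as skimage_otsu

from embryoquant.image import Roi
from embryoquant.segmentation import (
    Histogram,
    build_histogram,
    contrast_stretch,
    expand_roi,
    mask_to_roi,
    max_entropy_threshold,
    mean_filter,
    otsu_threshold,
    threshold_mask,
)

# ---------------------------------------------------------------------------
# independent exhaustive-search oracles (per-split, direct formulas)
# ---------------------------------------------------------------------------


def smallest_near_max(crits: list) -> int:
    # smallest split within rounding error of the maximum (exact-math ties
    # on symmetric histograms are broken toward the smallest level)
    m = max(crits)
    tol = 1e-10 * max(1.0, abs(m))
    return next(t for t, c in enumerate(crits) if c >= m - tol)


def otsu_exhaustive(counts: np.ndarray) -> int:
    counts = np.asarray(counts, dtype=float)
    levels = np.arange(len(counts), dtype=float)
    crits = []
    for t in range(len(counts) - 1):
        n0, n1 = counts[: t + 1].sum(), counts[t + 1 :].sum()
        if n0 == 0 or n1 == 0:
            crits.append(0.0)
        else:
            w0, w1 = n0 / counts.sum(), n1 / counts.sum()
            mu0 = (counts[: t + 1] * levels[: t + 1]).sum() / n0
            mu1 = (counts[t + 1 :] * levels[t + 1 :]).sum() / n1
            crits.append(w0 * w1 * (mu0 - mu1) ** 2)
    return smallest_near_max(crits)


def max_entropy_exhaustive(counts: np.ndarray) -> int:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()

    def side_entropy(side: np.ndarray) -> float:
        mass = side.sum()
        q = side[side > 0] / mass
        return float(-(q * np.log(q)).sum())

    crits = []
    for t in range(len(counts) - 1):
        if counts[: t + 1].sum() == 0 or counts[t + 1 :].sum() == 0:
            crits.append(-math.inf)  # only splits leaving both classes non-empty
            continue
        crits.append(
            side_entropy(counts[: t + 1] / total) + side_entropy(counts[t + 1 :] / total)
        )
    return smallest_near_max(crits)


def random_histograms(rng, n):
    for _ in range(n):
        n_bins = int(rng.choice([16, 64, 256]))
        if rng.random() < 0.5:
            counts = rng.integers(0, 30, size=n_bins)
        else:  # sparse: most bins empty, forces plateaus and the tie rule
            counts = np.zeros(n_bins, dtype=np.int64)
            occupied = rng.choice(n_bins, size=int(rng.integers(2, 6)), replace=False)
            counts[occupied] = rng.integers(1, 50, size=occupied.size)
        if np.count_nonzero(counts) < 2:
            counts[[0, n_bins - 1]] = 1
        yield Histogram(counts=counts, bin_edges=np.arange(n_bins + 1, dtype=float))


class TestHistogram:
    def test_extreme_levels_example(self):
        pixels = np.array([0, 0, 255], dtype=np.uint8)
        h = build_histogram(pixels, n_bins=256)
        assert h.counts[0] == 2 and h.counts[255] == 1 and h.total == 3

    def test_constant_pixels_single_bin(self):
        h = build_histogram(np.full(50, 7, dtype=np.uint8))
        assert h.counts.max() == 50 and np.count_nonzero(h.counts) == 1

    def test_counts_match_tally_loop(self, rng):
        pixels = rng.integers(0, 256, size=500).astype(np.uint8)
        h = build_histogram(pixels, n_bins=256)
        tally = {}
        for v in pixels:
            tally[int(v)] = tally.get(int(v), 0) + 1
        for level, count in tally.items():
            bin_idx = int(np.searchsorted(h.bin_edges, level, side="right") - 1)
            assert h.counts[bin_idx] == count
        assert h.total == 500

    def test_16bit_data_binned_over_min_max(self, rng):
        pixels = rng.integers(1000, 60000, size=1000).astype(np.uint16)
        h = build_histogram(pixels, n_bins=256)
        assert h.n_bins == 256
        assert h.bin_edges[0] == pixels.min() and h.bin_edges[-1] == pixels.max()
        assert h.total == 1000

    def test_zero_pixels_rejected(self):
        with pytest.raises(ValueError, match="zero pixels"):
            build_histogram(np.array([]))


class TestThresholds:
    @pytest.mark.parametrize(
        "impl,oracle",
        [(otsu_threshold, otsu_exhaustive), (max_entropy_threshold, max_entropy_exhaustive)],
        ids=["otsu", "max_entropy"],
    )
    def test_equals_exhaustive_search(self, impl, oracle, rng):
        for h in random_histograms(rng, 300):
            assert impl(h) == oracle(h.counts)

    @pytest.mark.parametrize(
        "impl", [otsu_threshold, max_entropy_threshold], ids=["otsu", "max_entropy"]
    )
    def test_two_delta_plateau_tie_breaks_to_smallest(self, impl):
        # every split between the two occupied levels gives the same classes;
        # the tie rule must choose the smallest level
        h = build_histogram(np.array([10, 10, 200, 200], dtype=np.uint8), n_bins=256)
        t = impl(h)
        assert h.level_value(t) == 10

    @pytest.mark.parametrize(
        "impl", [otsu_threshold, max_entropy_threshold], ids=["otsu", "max_entropy"]
    )
    def test_degenerate_histogram_rejected(self, impl):
        h = build_histogram(np.full(30, 42, dtype=np.uint8))
        with pytest.raises(ValueError, match="degenerate"):
            impl(h)

    @pytest.mark.parametrize(
        "impl", [otsu_threshold, max_entropy_threshold], ids=["otsu", "max_entropy"]
    )
    def test_invariant_under_count_duplication(self, impl, rng):
        for h in random_histograms(rng, 50):
            doubled = Histogram(counts=h.counts * 2, bin_edges=h.bin_edges)
            assert impl(h) == impl(doubled)

    def test_otsu_on_random_8bit_image_equals_exhaustive(self, rng):
        img = np.concatenate(
            [rng.integers(0, 80, 300), rng.integers(150, 256, 200)]
        ).astype(np.uint8)
        h = build_histogram(img)
        t = otsu_threshold(h)
        assert t == otsu_exhaustive(h.counts)

    def test_otsu_agrees_with_skimage_on_8bit_images(self, rng):
        # independent library implementation as a cross-check
        for _ in range(20):
            img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
            img[:16] //= 3
            h = build_histogram(img)
            assert h.level_value(otsu_threshold(h)) == skimage_otsu(img)

    def test_max_entropy_criterion_is_maximal_at_returned_split(self, rng):
        h = next(iter(random_histograms(rng, 1)))
        t = max_entropy_threshold(h)
        crits = [
            max_entropy_exhaustive_crit(h.counts, s)
            for s in range(h.n_bins - 1)
            if h.counts[: s + 1].sum() > 0 and h.counts[s + 1 :].sum() > 0
        ]
        assert max_entropy_exhaustive_crit(h.counts, t) >= max(crits) - 1e-12

    def test_foreground_is_strictly_greater_than_level(self):
        img = np.array([[10, 10, 200], [200, 10, 10]], dtype=np.uint8)
        h = build_histogram(img)
        t = otsu_threshold(h)
        mask = threshold_mask(img, h, t)
        np.testing.assert_array_equal(mask, img > h.level_value(t))


def max_entropy_exhaustive_crit(counts, t):
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()

    def side_entropy(side):
        mass = side.sum()
        if mass == 0:
            return 0.0
        q = side[side > 0] / mass
        return float(-(q * np.log(q)).sum())

    return side_entropy(counts[: t + 1] / total) + side_entropy(counts[t + 1 :] / total)


class TestMeanFilter:
    def test_constant_frame_is_fixed_point(self):
        frame = np.full((9, 9), 6.0)
        np.testing.assert_allclose(mean_filter(frame, 2), frame)

    def test_single_bright_pixel_spreads_over_cross_kernel(self):
        # r=1 disk = 5-member cross; interior pixel value 10 -> 2 at each member
        frame = np.zeros((7, 7))
        frame[3, 3] = 10.0
        out = mean_filter(frame, radius_px=1)
        assert out[3, 3] == pytest.approx(2.0)
        for y, x in [(2, 3), (4, 3), (3, 2), (3, 4)]:
            assert out[y, x] == pytest.approx(2.0)
        assert out[2, 2] == 0.0

    def test_matches_double_loop_neighbourhood_mean(self, rng):
        frame = rng.random((11, 13)) * 100
        r = 2
        out = mean_filter(frame, r)
        for y in range(11):
            for x in range(13):
                members = [
                    frame[y + dy, x + dx]
                    for dy in range(-r, r + 1)
                    for dx in range(-r, r + 1)
                    if dx * dx + dy * dy <= r * r
                    and 0 <= y + dy < 11
                    and 0 <= x + dx < 13
                ]
                assert out[y, x] == pytest.approx(np.mean(members))

    def test_output_stays_within_input_range(self, rng):
        frame = rng.random((20, 20)) * 500
        out = mean_filter(frame, 3)
        assert out.min() >= frame.min() - 1e-9 and out.max() <= frame.max() + 1e-9


class TestContrastStretch:
    def test_two_level_stretch(self):
        out = contrast_stretch(np.array([[10.0, 110.0]]))
        np.testing.assert_allclose(out, [[0.0, 255.0]])

    def test_full_range_frame_unchanged(self):
        frame = np.array([[0.0, 128.0], [255.0, 64.0]])
        np.testing.assert_allclose(contrast_stretch(frame), frame)

    def test_rank_preserving(self, rng):
        frame = rng.random((10, 10)) * 1000
        out = contrast_stretch(frame)
        np.testing.assert_array_equal(np.argsort(frame.ravel()), np.argsort(out.ravel()))

    def test_constant_frame_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="constant"):
            out = contrast_stretch(np.full((4, 4), 9.0))
        np.testing.assert_allclose(out, 9.0)


def flood_fill_components(mask):
    """Independent 8-connected labelling by breadth-first flood fill."""
    mask = mask.astype(bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for sy in range(mask.shape[0]):
        for sx in range(mask.shape[1]):
            if mask[sy, sx] and labels[sy, sx] == 0:
                current += 1
                stack = [(sy, sx)]
                labels[sy, sx] = current
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (
                                0 <= ny < mask.shape[0]
                                and 0 <= nx < mask.shape[1]
                                and mask[ny, nx]
                                and labels[ny, nx] == 0
                            ):
                                labels[ny, nx] = current
                                stack.append((ny, nx))
    return labels, current


class TestMaskToRoi:
    def test_single_component_returned_whole(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 2:5] = True
        roi = mask_to_roi(mask)
        np.testing.assert_array_equal(roi.mask, mask)

    def test_largest_of_two_components(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[0:5, 0:6] = True   # 30 px
        mask[8:11, 8:12] = True  # 12 px
        roi = mask_to_roi(mask, mode="largest_component")
        assert roi.area_px == 30 and roi.mask[0, 0]

    def test_seed_selects_nearer_smaller_component(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[0:5, 0:6] = True
        mask[8:11, 8:12] = True
        roi = mask_to_roi(mask, mode="nearest_to_seed", seed_point=(10, 9))
        assert roi.area_px == 12 and roi.mask[9, 9]

    def test_components_match_flood_fill_oracle(self, rng):
        mask = rng.random((20, 20)) < 0.35
        mask[0, 0] = True
        oracle_labels, n = flood_fill_components(mask)
        roi = mask_to_roi(mask, mode="largest_component")
        sizes = [(oracle_labels == i).sum() for i in range(1, n + 1)]
        best = 1 + int(np.argmax(sizes))
        np.testing.assert_array_equal(roi.mask, oracle_labels == best)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no foreground"):
            mask_to_roi(np.zeros((5, 5), dtype=bool))


class TestExpandRoi:
    def test_point_roi_becomes_11x11(self):
        roi = Roi.rectangle(20, 20, 1, 1)
        expanded = expand_roi(roi, 5, (50, 50))
        assert expanded.area_px == 121
        assert (expanded.x0, expanded.y0, expanded.width, expanded.height) == (15, 15, 11, 11)

    def test_border_expansion_is_clipped_but_contains_input(self):
        roi = Roi.rectangle(0, 0, 3, 3)
        expanded = expand_roi(roi, 5, (20, 20))
        assert expanded.area_px < 13 * 13
        assert expanded.contains(roi, (20, 20))

    def test_mask_expansion_matches_chebyshev_distance_test(self, rng):
        mask = rng.random((15, 15)) < 0.1
        mask[7, 7] = True
        roi = Roi.from_mask(mask)
        k = 3
        expanded = expand_roi(roi, k, mask.shape)
        for y in range(15):
            for x in range(15):
                cheb = min(
                    max(abs(y - yy), abs(x - xx))
                    for yy, xx in zip(*np.nonzero(mask))
                )
                assert expanded.mask[y, x] == (cheb <= k)

    def test_monotone_in_k(self, rng):
        mask = rng.random((15, 15)) < 0.1
        mask[7, 7] = True
        roi = Roi.from_mask(mask)
        e1 = expand_roi(roi, 1, mask.shape)
        e3 = expand_roi(roi, 3, mask.shape)
        assert e3.contains(e1, mask.shape)
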