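"""Unit and property tests for the threshold-segmentation family."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoventry.segmentation import (
    GrayImage,
    SegmentationError,
    between_within_variances,
    classify_pixels,
    decompose,
    dice_coefficient,
    global_otsu_segment,
    global_segment,
    hvs_segment,
    merge_masks,
    multi_segment,
    otsu_threshold,
    sobel_gradient,
    threshold_subimage,
    tiled_otsu_segment,
)


def brute_force_otsu(hist):
    """Independent exhaustive maximizer of the between-class variance.

    Uses exact rational arithmetic so plateau ties are compared without
    floating-point noise: v(t) = w0 w1 (m0 - m1)^2 with each term a Fraction.
    """
    from fractions import Fraction

    counts = [int(v) for v in np.asarray(hist)]
    n = sum(counts)
    best_t, best_v = 0, Fraction(-1)
    for t in range(len(counts) - 1):
        c0 = counts[: t + 1]
        c1 = counts[t + 1 :]
        n0, n1 = sum(c0), sum(c1)
        if n0 == 0 or n1 == 0:
            v = Fraction(0)
        else:
            w0 = Fraction(n0, n)
            w1 = Fraction(n1, n)
            m0 = Fraction(sum(g * c for g, c in enumerate(c0)), n0)
            m1 = Fraction(sum((t + 1 + g) * c for g, c in enumerate(c1)), n1)
            v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:  # strict: keeps the smallest maximizing t
            best_t, best_v = t, v
    return best_t


def to_image(values, **kw):
    return GrayImage(np.asarray(values, dtype=np.int64), **kw)


# ---------------------------------------------------------------------------
# Sobel gradient
# ---------------------------------------------------------------------------


class TestSobelGradient:
    def test_constant_image_has_zero_gradient(self):
        g = sobel_gradient(to_image(np.full((8, 8), 7)))
        assert np.all(g.S == 0) and g.S_avg == 0 and np.all(g.S_mu == 0)

    def test_vertical_step_center_magnitude(self):
        # columns (0, 0, 255): Gx = 4*255 = 1020, Gy = 0 at the center
        img = to_image(np.tile([0, 0, 255], (3, 1)))
        g = sobel_gradient(img)
        assert g.S[1, 1] == pytest.approx(1020.0)

    def test_isolated_center_pixel_has_zero_center_response(self):
        # both Sobel kernels carry zero center weight
        v = np.zeros((3, 3), dtype=np.int64)
        v[1, 1] = 255
        assert sobel_gradient(to_image(v)).S[1, 1] == 0.0

    def test_summary_statistics_are_consistent(self, rng):
        img = to_image(rng.integers(0, 256, size=(16, 16)))
        g = sobel_gradient(img)
        assert g.S_avg == pytest.approx(g.S.mean())
        # window means stay within the local min/max envelope
        from scipy.ndimage import maximum_filter, minimum_filter

        lo = minimum_filter(g.S, 3, mode="nearest")
        hi = maximum_filter(g.S, 3, mode="nearest")
        assert np.all(g.S_mu >= lo - 1e-9) and np.all(g.S_mu <= hi + 1e-9)

    def test_too_small_image_rejected(self):
        with pytest.raises(SegmentationError):
            to_image(np.zeros((2, 5)))


# ---------------------------------------------------------------------------
# pixel classification
# ---------------------------------------------------------------------------


class TestClassifyPixels:
    def test_constant_image_all_remainder(self):
        labels = classify_pixels(sobel_gradient(to_image(np.full((8, 8), 42))))
        assert not labels.detail.any()
        assert np.all(labels.labels == 2)

    def test_step_edge_detail_band_hugs_the_edge(self):
        v = np.zeros((16, 16), dtype=np.int64)
        v[:, 8:] = 200
        labels = classify_pixels(sobel_gradient(to_image(v)))
        det_cols = np.flatnonzero(labels.detail.any(axis=0))
        assert det_cols.size > 0
        assert det_cols.min() >= 6 and det_cols.max() <= 9  # band along the edge
        assert not labels.detail[:, :5].any() and not labels.detail[:, 11:].any()

    def test_impulse_noise_classified_less_than_step_edge(self):
        step = np.zeros((16, 16), dtype=np.int64)
        step[:, 8:] = 200
        frac_step = classify_pixels(sobel_gradient(to_image(step))).detail.mean()
        impulse = np.zeros((16, 16), dtype=np.int64)
        impulse[8, 8] = 200
        frac_imp = classify_pixels(sobel_gradient(to_image(impulse))).detail.mean()
        assert frac_imp <= frac_step


# ---------------------------------------------------------------------------
# Otsu threshold
# ---------------------------------------------------------------------------


class TestOtsuThreshold:
    def test_two_extreme_values_tie_resolves_to_zero(self):
        hist = np.bincount([0, 0, 255, 255], minlength=256)
        res = otsu_threshold(hist)
        assert res.threshold == 0 and not res.degenerate

    def test_plateau_tie_resolves_to_smallest(self):
        hist = np.bincount([50] * 10 + [200] * 10, minlength=256)
        assert otsu_threshold(hist).threshold == 50

    def test_single_value_degenerate(self):
        hist = np.bincount([77] * 9, minlength=256)
        res = otsu_threshold(hist)
        assert res.threshold == 77 and res.degenerate

    def test_empty_histogram_rejected(self):
        with pytest.raises(SegmentationError):
            otsu_threshold(np.zeros(256))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 63), min_size=2, max_size=200))
    def test_matches_brute_force_including_ties(self, values):
        hist = np.bincount(values, minlength=64)
        res = otsu_threshold(hist)
        if len(set(values)) == 1:
            assert res.degenerate
        else:
            assert res.threshold == brute_force_otsu(hist)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 31), min_size=2, max_size=100),
        st.integers(0, 30),
    )
    def test_variance_decomposition_identity(self, values, t):
        hist = np.bincount(values, minlength=32)
        between, within, total = between_within_variances(hist, t)
        assert between + within == pytest.approx(total, abs=1e-9)

    def test_agrees_with_skimage_on_clean_bimodal_data(self, rng):
        from skimage.filters import threshold_otsu

        values = np.concatenate(
            [rng.normal(60, 6, 400), rng.normal(180, 8, 300)]
        )
        values = np.clip(np.round(values), 0, 255).astype(np.int64)
        ours = otsu_threshold(np.bincount(values, minlength=256)).threshold
        theirs = threshold_otsu(values)
        # conventions differ by at most one bin around the valley
        assert abs(ours - theirs) <= 1


# ---------------------------------------------------------------------------
# thresholded maps
# ---------------------------------------------------------------------------


class TestSegmentMaps:
    def test_max_threshold_gives_all_zeros(self):
        img = to_image([[0, 100, 255]] * 3)
        assert not global_segment(img, 255).any()

    def test_zero_threshold_on_binary_values(self):
        img = to_image([[0, 0, 255], [255, 0, 0], [0, 0, 0]])
        assert global_segment(img, 0).sum() == 2

    def test_threshold_separates_phantom_tissue(self, clean_phantom):
        truth = clean_phantom.brain_mask & ~clean_phantom.ventricle_mask
        B = global_segment(clean_phantom.image, 100)  # between CSF 60 / tissue 150
        assert np.array_equal(B.astype(bool), truth)

    def test_single_threshold_consistent_with_global(self, rng):
        img = to_image(rng.integers(0, 256, (8, 8)))
        assert np.array_equal(multi_segment(img, [128]), global_segment(img, 128))

    def test_two_thresholds_three_classes(self):
        img = to_image([[0, 100, 200]] * 3)
        out = multi_segment(img, [50, 150])
        assert np.array_equal(out, [[0, 1, 2]] * 3)

    def test_nonascending_thresholds_rejected(self):
        img = to_image(np.zeros((3, 3), dtype=np.int64))
        with pytest.raises(SegmentationError):
            multi_segment(img, [100, 100])

    def test_multi_threshold_recovers_phantom_classes(self, clean_phantom):
        # thresholds between the three scene modes (bg 15 / CSF 60 / tissue 150)
        out = multi_segment(clean_phantom.image, [40, 100])
        vent = clean_phantom.ventricle_mask
        tissue = clean_phantom.brain_mask & ~vent
        bg = ~clean_phantom.brain_mask
        assert np.all(out[bg] == 0) and np.all(out[vent] == 1) and np.all(out[tissue] == 2)


# ---------------------------------------------------------------------------
# decomposition / sub-image thresholds / merge
# ---------------------------------------------------------------------------


class TestDecomposeAndMerge:
    def test_all_remainder_label_map_gives_empty_detail_subimage(self):
        img = to_image(np.full((5, 5), 9))
        labels = classify_pixels(sobel_gradient(img))
        I1, I2 = decompose(img, labels, 9)
        assert not I1.any() and I2.all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_masks_always_partition(self, seed):
        r = np.random.default_rng(seed)
        img = to_image(r.integers(0, 256, (6, 6)))
        labels = classify_pixels(sobel_gradient(img))
        I1, I2 = decompose(img, labels, 100)
        assert not np.any(I1 & I2) and np.all(I1 | I2)

    def test_whole_image_membership_reduces_to_global_otsu(self, rng):
        img = to_image(rng.integers(0, 256, (8, 8)))
        T, B = threshold_subimage(img, np.ones((8, 8), bool), fallback_T=0)
        T_ref, B_ref = global_otsu_segment(img)
        assert T == T_ref and np.array_equal(B, B_ref)

    def test_four_member_exhaustive_example(self):
        img = to_image([[0, 0, 255], [255, 7, 7], [7, 7, 7]])
        members = img.values != 7
        T, B = threshold_subimage(img, members, fallback_T=0)
        assert T == 0 and B.sum() == 2 and not B[~members].any()

    def test_degenerate_members_use_fallback(self):
        img = to_image(np.full((4, 4), 100))
        members = np.zeros((4, 4), bool)
        members[:2] = True
        T, B = threshold_subimage(img, members, fallback_T=90)
        assert T == 90 and np.array_equal(B.astype(bool), members)

    def test_empty_members_warn_and_fall_back(self):
        img = to_image(np.arange(16).reshape(4, 4))
        with pytest.warns(UserWarning):
            T, B = threshold_subimage(img, np.zeros((4, 4), bool), fallback_T=5)
        assert T == 5 and not B.any()

    def test_empty_detail_merge_returns_remainder_map(self):
        I1 = np.zeros((4, 4), bool)
        I2 = ~I1
        B2 = np.eye(4, dtype=np.uint8)
        assert np.array_equal(merge_masks(np.zeros((4, 4), np.uint8), B2, I1, I2), B2)

    def test_complementary_constant_maps_merge_to_detail_mask(self, rng):
        I1 = rng.random((6, 6)) < 0.5
        I2 = ~I1
        B = merge_masks(I1.astype(np.uint8), np.zeros((6, 6), np.uint8), I1, I2)
        assert np.array_equal(B.astype(bool), I1)

    def test_overlapping_masks_rejected(self):
        ones = np.ones((3, 3), bool)
        with pytest.raises(SegmentationError):
            merge_masks(ones, ones, ones, ones)


# ---------------------------------------------------------------------------
# the full hybrid pipeline
# ---------------------------------------------------------------------------


class TestHvsSegment:
    def test_noise_free_two_class_slice_dice(self):
        # tissue ellipse on background, partial-volume blur only
        from scipy.ndimage import gaussian_filter

        r = np.arange(128)[:, None]
        c = np.arange(128)[None, :]
        ellipse = ((r - 63.5) / 55.0) ** 2 + ((c - 63.5) / 40.0) ** 2 <= 1
        scene = np.where(ellipse, 150.0, 15.0)
        img = GrayImage(np.round(gaussian_filter(scene, 1.0)).astype(np.int64))
        res = hvs_segment(img)
        assert dice_coefficient(res.B, ellipse) >= 0.99

    def test_merge_consistency_on_noisy_phantoms(self, noisy_phantoms):
        for ph in noisy_phantoms[:20]:
            res = hvs_segment(ph.image)
            assert np.array_equal(res.B[res.I1_mask], res.B1[res.I1_mask])
            assert np.array_equal(res.B[res.I2_mask], res.B2[res.I2_mask])
            assert not res.B1[res.I2_mask].any()
            assert not res.B2[res.I1_mask].any()

    def test_deterministic_bit_identical(self, noisy_phantoms):
        img = noisy_phantoms[0].image
        a, b = hvs_segment(img), hvs_segment(img)
        assert a.T_otsu == b.T_otsu and a.T1 == b.T1 and a.T2 == b.T2
        assert np.array_equal(a.B, b.B)
        assert np.array_equal(a.label_map.detail, b.label_map.detail)

    def test_constant_gray_shift_leaves_binary_map_unchanged(self, noisy_phantoms):
        img = noisy_phantoms[0].image
        shifted = GrayImage(
            img.values + 40, pixel_spacing=img.pixel_spacing, gray_levels=512
        )
        a = hvs_segment(img)
        b = hvs_segment(shifted)
        assert b.T_otsu == a.T_otsu + 40
        assert np.array_equal(a.B, b.B)

    def test_invert_flag_complements_the_map(self, noisy_phantoms):
        img = noisy_phantoms[0].image
        a = hvs_segment(img)
        b = hvs_segment(img, invert=True)
        assert np.array_equal(a.B + b.B, np.ones_like(a.B))

    def test_tiled_baseline_runs_and_differs_from_global(self, noisy_phantoms):
        img = noisy_phantoms[0].image
        B = tiled_otsu_segment(img, tile_size=32)
        assert B.shape == img.shape and set(np.unique(B)) <= {0, 1}


class TestDice:
    def test_identical_masks_give_one_and_disjoint_zero(self):
        a = np.zeros((4, 4), bool)
        a[:2] = True
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, ~a) == 0.0
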