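"""Texture descriptor families: examples, oracles and dimensional contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sheartex.descriptors import (
    HARALICK_NAMES,
    box_counting_dimension,
    cm_features,
    cmdot_features,
    cmdot_subband,
    cooccurrence_mean,
    haralick20,
    lbp_features,
    lbp_riu2,
    losib,
    losib_features,
    multiotsu_thresholds,
    quantize_subband,
    sfta,
    sfta_features,
    sfta_region_features,
    ttbd,
)
from sheartex.errors import ContractError, DataError


def brute_force_haralick(p):
    """Independent double-sum implementation of the 20 CM statistics."""
    ng = p.shape[0]
    out = {}
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    def ent(values):
        return -sum(v * math.log(v) for v in values if v > 0)

    out["contrast"] = sum(
        (i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
    )
    if var_x > 0 and var_y > 0:
        out["correlation"] = sum(
            (i + 1 - mu_x) * (j + 1 - mu_y) * p[i][j]
            for i in range(ng)
            for j in range(ng)
        ) / math.sqrt(var_x * var_y)
    else:
        out["correlation"] = 0.0
    out["energy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    out["autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)
    )
    out["cluster_prominence"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 4 * p[i][j]
        for i in range(ng)
        for j in range(ng)
    )
    out["cluster_shade"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 3 * p[i][j]
        for i in range(ng)
        for j in range(ng)
    )
    out["dissimilarity"] = sum(
        abs(i - j) * p[i][j] for i in range(ng) for j in range(ng)
    )
    out["entropy"] = ent(p.ravel())
    out["homogeneity"] = sum(
        p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    out["maximum_probability"] = max(p[i][j] for i in range(ng) for j in range(ng))
    cm_mean = float(np.mean(p))
    out["sum_of_squares"] = sum(
        (i + 1 - cm_mean) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
    )
    out["variance"] = sum(
        (i + 1 - mu_x) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
    )
    out["sum_average"] = sum(k * v for k, v in p_sum.items())
    out["sum_variance"] = sum(
        (k - out["sum_average"]) ** 2 * v for k, v in p_sum.items()
    )
    out["sum_entropy"] = ent(list(p_sum.values()))
    mu_d = sum(k * v for k, v in p_diff.items())
    out["difference_variance"] = sum(
        (k - mu_d) ** 2 * v for k, v in p_diff.items()
    )
    out["difference_entropy"] = ent(list(p_diff.values()))
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        p[i][j] * math.log(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if p[i][j] > 0 and px[i] * py[j] > 0
    )
    out["information_measure_of_correlation"] = (
        (out["entropy"] - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    )
    out["inverse_difference_normalized"] = sum(
        p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    out["inverse_difference_moment_normalized"] = sum(
        p[i][j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
    )
    return np.array([out[name] for name in HARALICK_NAMES])


def random_cooc(rng, ng=4):
    """Random symmetric normalized co-occurrence matrix."""
    m = rng.random((ng, ng))
    m = m + m.T
    return m / m.sum()


class TestQuantize:
    def test_constant_maps_to_level_one(self):
        np.testing.assert_array_equal(quantize_subband(np.full((4, 4), 3.3)), 1)

    def test_two_values_two_levels(self):
        band = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(
            quantize_subband(band, 2), np.array([[1, 2], [2, 1]])
        )

    def test_linspace_hits_every_level_once(self):
        levels = quantize_subband(np.linspace(0, 1, 8).reshape(2, 4), 8)
        np.testing.assert_array_equal(np.sort(levels.ravel()), np.arange(1, 9))

    def test_non_finite_rejected(self):
        with pytest.raises(DataError):
            quantize_subband(np.array([[np.nan, 0.0], [0.0, 0.0]]))

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(2, 16))
    def test_levels_bounded(self, seed, ng):
        band = np.random.default_rng(seed).standard_normal((6, 6))
        levels = quantize_subband(band, ng)
        assert levels.min() >= 1 and levels.max() <= ng


class TestCooccurrence:
    def test_constant_subband_all_mass_at_origin(self):
        cm = cooccurrence_mean(quantize_subband(np.full((4, 4), 1.0)), 8)
        assert cm.p[0, 0] == pytest.approx(1.0)
        assert cm.p.sum() == pytest.approx(1.0)

    def test_checkerboard_zero_diagonal_horizontally(self):
        levels = np.array([[1, 2], [2, 1]])
        from skimage.feature import graycomatrix

        glcm = graycomatrix(
            (levels - 1).astype(np.uint8), [1], [0.0], levels=2,
            symmetric=True, normed=True,
        )[:, :, 0, 0]
        # oracle: enumerate horizontal neighbour pairs -> all cross-level
        assert glcm[0, 0] == 0 and glcm[1, 1] == 0
        assert glcm[0, 1] == pytest.approx(0.5)

    def test_normalized_and_symmetric(self):
        rng = np.random.default_rng(3)
        cm = cooccurrence_mean(quantize_subband(rng.random((16, 16)), 8), 8)
        assert cm.p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(cm.p, cm.p.T, atol=1e-15)

    def test_too_small_subband_rejected(self):
        with pytest.raises(DataError):
            cooccurrence_mean(np.ones((1, 1), dtype=int), 8)


class TestHaralick20:
    def test_single_cell_distribution(self):
        cm = np.zeros((8, 8))
        cm[0, 0] = 1.0
        stats = dict(zip(HARALICK_NAMES, haralick20(cm)))
        assert stats["contrast"] == 0
        assert stats["energy"] == 1
        assert stats["maximum_probability"] == 1
        assert stats["dissimilarity"] == 0
        assert stats["homogeneity"] == 1

    def test_uniform_two_level_closed_form(self):
        stats = dict(zip(HARALICK_NAMES, haralick20(np.full((2, 2), 0.25))))
        assert stats["energy"] == pytest.approx(0.25)
        assert stats["entropy"] == pytest.approx(np.log(4))

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = random_cooc(rng, ng=4)
            np.testing.assert_allclose(
                haralick20(p), brute_force_haralick(p), atol=1e-10
            )

    def test_always_finite_even_for_degenerate_matrices(self):
        cm = np.zeros((8, 8))
        cm[2, 2] = 1.0  # constant subband: zero marginal variance
        assert np.all(np.isfinite(haralick20(cm)))

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ContractError):
            haralick20(np.ones((4, 4)))

    def test_block_length_and_names(self, coeff_stack64):
        block = cm_features(
            coeff_stack64.magnitude, "magnitude", coeff_stack64.subband_index
        )
        assert len(block) == 640
        assert len(set(block.column_names)) == 640
        assert block.column_names[0] == "cm.magnitude.s1.k1.contrast"

    def test_toy_stack_length(self):
        rng = np.random.default_rng(0)
        block = cm_features(rng.random((2, 16, 16)), "rp", [(1, 1), (1, 2)])
        assert len(block) == 40


class TestLBP:
    def test_constant_subband_single_bin(self):
        hist = lbp_riu2(np.full((16, 16), 2.5))
        assert hist[8] == pytest.approx(1.0)
        assert np.count_nonzero(hist) == 1

    def test_histogram_normalized_length_p_plus_2(self):
        hist = lbp_riu2(np.random.default_rng(5).standard_normal((32, 32)))
        assert len(hist) == 10
        assert hist.sum() == pytest.approx(1.0)

    def test_rotation_invariance_under_90_degrees(self):
        band = np.random.default_rng(6).standard_normal((32, 32))
        np.testing.assert_allclose(
            lbp_riu2(band), lbp_riu2(np.rot90(band)), atol=1e-12
        )

    def test_scale_invariance(self):
        band = np.random.default_rng(7).standard_normal((32, 32))
        np.testing.assert_allclose(lbp_riu2(band), lbp_riu2(5.0 * band))

    def test_too_small_band_rejected(self):
        with pytest.raises(DataError):
            lbp_riu2(np.zeros((4, 4)))

    def test_block_length(self, coeff_stack64):
        block = lbp_features(
            coeff_stack64.magnitude, "magnitude", coeff_stack64.subband_index
        )
        assert len(block) == 320

    def test_constant_stack_has_one_nonzero_per_subband(self):
        block = lbp_features(np.ones((32, 16, 16)), "magnitude")
        assert np.count_nonzero(block.values) == 32


class TestLOSIB:
    def test_constant_subband_all_zero(self):
        np.testing.assert_array_equal(losib(np.full((8, 8), 1.7)), 0.0)

    def test_vertical_step_only_horizontal_directions_respond(self):
        band = np.zeros((8, 8))
        band[:, 4:] = 1.0
        mu = losib(band)
        # directions 0 (E) and 4 (W) cross the step; 2 (N) and 6 (S) do not
        assert mu[0] > 0 and mu[4] > 0
        assert mu[2] == 0 and mu[6] == 0

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(8)
        band = rng.standard_normal((9, 7))
        offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
        expected = []
        for dy, dx in offsets:
            acc, n = 0.0, 0
            for i in range(1, 8):
                for j in range(1, 6):
                    acc += abs(band[i, j] - band[i + dy, j + dx])
                    n += 1
            expected.append(acc / n)
        np.testing.assert_allclose(losib(band), expected, atol=1e-12)

    def test_nonnegative_and_scales_linearly(self):
        band = np.random.default_rng(9).standard_normal((12, 12))
        mu = losib(band)
        assert np.all(mu >= 0)
        np.testing.assert_allclose(losib(3.0 * band), 3.0 * mu, atol=1e-12)

    def test_block_length(self, coeff_stack64):
        block = losib_features(
            coeff_stack64.magnitude, "magnitude", coeff_stack64.subband_index
        )
        assert len(block) == 256

    def test_zero_stack_gives_zero_vector(self):
        block = losib_features(np.zeros((2, 8, 8)), "rp", [(1, 1), (1, 2)])
        assert len(block) == 16
        np.testing.assert_array_equal(block.values, 0.0)


class TestMultiOtsu:
    def test_matches_skimage_objective(self):
        """The DP thresholds attain at least skimage's between-class variance."""
        from skimage.filters import threshold_multiotsu

        rng = np.random.default_rng(10)
        vals = (rng.random((64, 64)) ** 2 * 255).astype(np.int64).clip(0, 255)

        def between_class_variance(th):
            cls = np.digitize(vals.ravel(), th)
            mu = vals.mean()
            return sum(
                (vals.ravel()[cls == c].size / vals.size)
                * (vals.ravel()[cls == c].mean() - mu) ** 2
                for c in np.unique(cls)
            )

        mine = multiotsu_thresholds(vals, 4, 256)
        theirs = threshold_multiotsu(vals.astype(np.uint8), classes=5, nbins=256)
        assert between_class_variance(mine) >= between_class_variance(theirs + 0.5) - 1e-9

    def test_bimodal_threshold_between_modes(self):
        vals = np.concatenate([np.full(100, 10), np.full(100, 200)])
        th = multiotsu_thresholds(vals, 1, 256)
        assert 10 < th[0] < 200


class TestSFTA:
    def test_ttbd_binary_counts(self):
        band = np.random.default_rng(11).random((32, 32))
        assert len(ttbd(band, nt=4)) == 7
        assert len(ttbd(band, nt=2)) == 3

    def test_constant_band_fallback_all_zero(self):
        binaries = ttbd(np.full((32, 32), 0.4), nt=4)
        assert len(binaries) == 7
        assert not any(b.any() for b in binaries)

    def test_empty_region_features_are_zero(self):
        np.testing.assert_array_equal(
            sfta_region_features(np.zeros((16, 16), dtype=bool), np.zeros((16, 16))),
            0.0,
        )

    def test_full_ones_pixel_count(self):
        feats = sfta_region_features(np.ones((64, 64), dtype=bool), np.ones((64, 64)))
        assert feats[2] == 4096

    def test_square_outline_fractal_dimension_near_one(self):
        binary = np.zeros((64, 64), dtype=bool)
        binary[16:48, 16:48] = True
        border_dim = sfta_region_features(binary, np.ones((64, 64)))[0]
        assert border_dim == pytest.approx(1.0, abs=0.15)

    def test_filled_plane_dimension_near_two(self):
        assert box_counting_dimension(np.ones((64, 64), dtype=bool)) == pytest.approx(
            2.0, abs=0.1
        )

    def test_per_subband_and_stack_lengths(self, coeff_stack64):
        band = coeff_stack64.magnitude[5]
        assert len(sfta(band)) == 21
        block = sfta_features(
            coeff_stack64.magnitude, "magnitude", coeff_stack64.subband_index
        )
        assert len(block) == 672

    def test_zero_stack_gives_zero_vector(self):
        block = sfta_features(np.zeros((2, 32, 32)), "rp", [(1, 1), (1, 2)])
        np.testing.assert_array_equal(block.values, 0.0)

    def test_scale_invariance_of_sfta_vector(self):
        band = np.random.default_rng(12).random((64, 64))
        np.testing.assert_allclose(sfta(band), sfta(4.0 * band + 2.0), atol=1e-12)


class TestCMDot:
    def test_zero_magnitude_gives_zero_vector(self):
        block = cmdot_features(np.zeros((2, 16, 16)), "magnitude", [(1, 1), (1, 2)])
        np.testing.assert_array_equal(block.values, 0.0)

    def test_toy_subband_matches_reference_construction(self):
        rng = np.random.default_rng(13)
        band = rng.random((8, 8))
        # independent reference: quantize, average 4 symmetric GLCMs, block
        # means (here 1x1 blocks since 8x8 / ng=8), column-wise maxima
        from skimage.feature import graycomatrix

        lo, hi = band.min(), band.max()
        levels = np.minimum((band - lo) / (hi - lo) * 8, 7.999).astype(int)
        glcm = graycomatrix(
            levels.astype(np.uint8), [1],
            [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=8, symmetric=True, normed=True,
        )[:, :, 0, :].mean(axis=-1)
        glcm = glcm / glcm.sum()
        expected = (glcm * band).max(axis=0)
        np.testing.assert_allclose(cmdot_subband(band, 8), expected, atol=1e-12)

    def test_rp_component_rejected(self):
        with pytest.raises(ContractError):
            cmdot_features(np.zeros((1, 16, 16)), "rp", [(1, 1)])

    def test_length_is_ng_per_subband(self, coeff_stack64):
        block = cmdot_features(
            coeff_stack64.magnitude, "magnitude", coeff_stack64.subband_index
        )
        assert len(block) == 32 * 8


class TestDeterminism:
    def test_descriptor_families_are_bit_reproducible(self, coeff_stack64):
        stack = coeff_stack64.magnitude[:4]
        idx = coeff_stack64.subband_index[:4]
        for fn in (cm_features, lbp_features, losib_features, sfta_features):
            a = fn(stack, "magnitude", idx)
            b = fn(stack, "magnitude", idx)
            np.testing.assert_array_equal(a.values, b.values)

    def test_cm_and_lbp_invariant_to_positive_scaling(self, coeff_stack64):
        stack = coeff_stack64.magnitude[:2]
        idx = coeff_stack64.subband_index[:2]
        np.testing.assert_allclose(
            cm_features(stack, "magnitude", idx).values,
            cm_features(7.0 * stack, "magnitude", idx).values,
            atol=1e-12,
        )
        np.testing.assert_allclose(
            lbp_features(stack, "magnitude", idx).values,
            lbp_features(7.0 * stack, "magnitude", idx).values,
            atol=1e-12,
        )
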