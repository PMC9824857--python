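"""Metric identities, SSIM semantics and the border-inflation artifact."""

import warnings

import numpy as np
import pytest

from yieldreg2d.evaluation import (compare_maps, dynamic_range, pearson_r,
                                   rmedse, rmse, square_error_map, ssim_index,
                                   ssim_map, ssim_mean, total_variation)


def _maps(rng, H=16, W=16, mask_frac=0.3):
    M = rng.random((H, W)) * 100
    P = M + rng.standard_normal((H, W)) * 5
    F = rng.random((H, W)) > mask_frac
    F[H // 2, W // 2] = True
    return M, P, F


class TestErrorMetrics:
    def test_perfect_prediction(self, rng):
        M, _, F = _maps(rng)
        assert rmse(M, M, F) == 0.0
        assert rmedse(M, M, F) == 0.0

    def test_two_cell_hand_computation(self):
        M = np.array([[3.0, 4.0]])
        P = np.zeros((1, 2))
        F = np.ones((1, 2), dtype=bool)
        assert rmse(M, P, F) == pytest.approx(np.sqrt(25 / 2))
        assert rmedse(M, P, F) == pytest.approx(np.sqrt((9 + 16) / 2))

    def test_median_robust_to_single_outlier(self):
        M = np.zeros((1, 9))
        P = M.copy()
        P[0, 0] = 50.0
        F = np.ones((1, 9), dtype=bool)
        assert rmedse(M, P, F) == 0.0
        assert rmse(M, P, F) > 0.0

    def test_empty_field_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            rmse(np.zeros((2, 2)), np.zeros((2, 2)),
                 np.zeros((2, 2), dtype=bool))

    def test_square_error_map_mean_is_rmse_squared(self, rng):
        M, P, F = _maps(rng)
        sq = square_error_map(M, P, F)
        assert np.nanmean(sq[F]) == pytest.approx(rmse(M, P, F) ** 2)
        assert np.all(np.isnan(sq[~F]))


class TestPearson:
    def test_positive_affine_transform_gives_one(self, rng):
        M, _, F = _maps(rng)
        assert pearson_r(M, 2 * M + 7, F) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, rng):
        M, _, F = _maps(rng)
        assert pearson_r(M, -M, F) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        M = np.array([[1.0, 2.0, 3.0, 4.0]])
        P = np.array([[2.0, 1.0, 4.0, 3.0]])
        F = np.ones((1, 4), dtype=bool)
        assert pearson_r(M, P, F) == pytest.approx(0.6)

    def test_constant_map_warns_and_returns_nan(self):
        M = np.ones((2, 2))
        P = np.random.default_rng(0).random((2, 2))
        F = np.ones((2, 2), dtype=bool)
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(pearson_r(M, P, F))

    def test_affine_invariance_property(self, rng):
        M, P, F = _maps(rng)
        base = pearson_r(M, P, F)
        for a, b in [(0.5, -3.0), (10.0, 100.0)]:
            assert pearson_r(M, a * P + b, F) == pytest.approx(base)


class TestSsimIndex:
    def test_identical_windows_score_one(self, rng):
        a = rng.random((3, 3)) * 50
        assert ssim_index(a, a, L=100.0) == pytest.approx(1.0, abs=1e-9)

    def test_anticorrelated_windows_near_minus_one(self):
        a = np.array([[40.0, -40.0], [-40.0, 40.0]]) * 100
        assert ssim_index(a, -a, L=100.0) < -0.99

    def test_constant_windows_closed_form(self):
        """sigma = 0 reduces the index to the luminance term:
        (2*10*20 + C1)*C2 / ((100+400+C1)*C2) with C1 = 1, C2 = 9."""
        a, b = np.full((3, 3), 10.0), np.full((3, 3), 20.0)
        expected = (2 * 10 * 20 + 1.0) / (100 + 400 + 1.0)
        assert ssim_index(a, b, L=100.0) == pytest.approx(expected)

    def test_symmetry(self, rng):
        a, b = rng.random((5, 5)), rng.random((5, 5))
        assert ssim_index(a, b, 1.0) == pytest.approx(ssim_index(b, a, 1.0))

    def test_invalid_dynamic_range_raises(self):
        with pytest.raises(ValueError, match="L"):
            ssim_index(np.zeros((2, 2)), np.zeros((2, 2)), L=0.0)


class TestSsimMap:
    def test_identical_maps_score_one_everywhere(self, rng):
        M, _, F = _maps(rng)
        smap = ssim_map(M, M, F, 3)
        np.testing.assert_allclose(smap[F], 1.0, atol=1e-9)
        assert ssim_mean(smap, F) == pytest.approx(1.0, abs=1e-9)

    def test_even_window_raises(self, rng):
        M, P, F = _maps(rng)
        with pytest.raises(ValueError, match="odd"):
            ssim_map(M, P, F, 4)

    def test_three_by_three_map_reduces_to_single_window(self, rng):
        """With w = 3 on a fully valid 3x3 map, the center pixel's window
        is the whole map, so it must equal the single-window index."""
        M = rng.random((3, 3)) * 10
        P = rng.random((3, 3)) * 10
        F = np.ones((3, 3), dtype=bool)
        L = dynamic_range(M, F)
        smap = ssim_map(M, P, F, 3, L=L)
        assert smap[1, 1] == pytest.approx(ssim_index(M, P, L))

    def test_interior_matches_skimage_oracle(self, rng):
        """Independent oracle: scikit-image's SSIM with a uniform window
        and population statistics agrees on interior pixels, where the
        border padding convention cannot differ."""
        from skimage.metrics import structural_similarity

        M, P, F = _maps(rng, mask_frac=0.0)     # fully valid field
        F[:] = True
        L = dynamic_range(M, F)
        for w in (3, 11):
            ours = ssim_map(M, P, F, w, L=L)
            _, ref = structural_similarity(
                M, P, win_size=w, data_range=L, gaussian_weights=False,
                use_sample_covariance=False, full=True)
            h = w // 2
            np.testing.assert_allclose(ours[h:-h, h:-h], ref[h:-h, h:-h],
                                       atol=1e-10)

    def test_border_inflation_with_disagreeing_interior(self, rng):
        """Windows near the field border include zero-valued out-of-field
        pixels at identical positions in both maps, which makes them score
        higher than interior windows when the interior disagrees."""
        from scipy import ndimage

        H = W = 20
        F = np.zeros((H, W), dtype=bool)
        F[4:-4, 4:-4] = True
        M = np.where(F, 80 + 20 * rng.random((H, W)), 0.0)
        P = np.where(F, 80 + 20 * rng.random((H, W)), 0.0)  # uncorrelated
        smap = ssim_map(M, P, F, 11)
        border = F & ~ndimage.binary_erosion(F)   # outermost field ring
        interior = ndimage.binary_erosion(F, iterations=4)
        assert smap[border].mean() > smap[interior].mean()

    def test_bounded_by_map_extrema(self, rng):
        M, P, F = _maps(rng)
        smap = ssim_map(M, P, F, 3)
        mean = ssim_mean(smap, F)
        assert smap[F].min() <= mean <= smap[F].max()


class TestCompareMaps:
    def test_metric_bundle_consistency(self, rng):
        M, P, F = _maps(rng)
        cmp_ = compare_maps(M, P, F)
        assert cmp_.metrics["SSIM3*"] == pytest.approx(
            100 * cmp_.metrics["SSIM3"])
        assert cmp_.metrics["RMSE"] == pytest.approx(rmse(M, P, F))
        assert -1 <= cmp_.metrics["r"] <= 1


class TestTotalVariation:
    def test_smoothing_reduces_tv(self, rng):
        from scipy import ndimage

        P = rng.random((20, 20))
        F = np.ones((20, 20), dtype=bool)
        smoothed = ndimage.uniform_filter(P, 3)
        assert total_variation(smoothed, F) < total_variation(P, F)

    def test_constant_map_has_zero_tv(self):
        assert total_variation(np.ones((5, 5)),
                               np.ones((5, 5), dtype=bool)) == 0.0
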