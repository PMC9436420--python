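"""Metric correctness against brute-force loop oracles and closed forms."""

import math

import numpy as np
import pytest
from scipy import stats as scipy_stats

from ctrestore.io import ContourMask
from ctrestore.metrics import (dsc, effective_dose, evaluate_volumes, hd95,
                               mae, mse, paired_t_report, psnr,
                               relative_change, ssim)


# ------------------------------------------------------------- loop oracles
def _loop_mae(X, Y):
    total = 0.0
    for x, y in zip(X.ravel(), Y.ravel()):
        total += abs(x - y)
    return total / X.size


def _loop_mse(X, Y):
    total = 0.0
    for x, y in zip(X.ravel(), Y.ravel()):
        total += abs(x - y) ** 2
    return total / X.size


def _loop_ssim_global(X, Y, C1, C2):
    m = X.size
    mx = sum(X.ravel()) / m
    my = sum(Y.ravel()) / m
    vx = sum((x - mx) ** 2 for x in X.ravel()) / m
    vy = sum((y - my) ** 2 for y in Y.ravel()) / m
    cov = sum((x - mx) * (y - my) for x, y in zip(X.ravel(), Y.ravel())) / m
    return ((2 * mx * my + C1) * (2 * cov + C2)) \
        / ((mx ** 2 + my ** 2 + C1) * (vx + vy + C2))


class TestErrorMetrics:
    def test_identical_images_have_zero_error(self, rng):
        X = rng.random((8, 8))
        assert mae(X, X) == 0.0
        assert mse(X, X) == 0.0

    def test_constant_offset(self, rng):
        X = rng.random((10, 10))
        assert mae(X + 5.0, X) == pytest.approx(5.0)
        assert mse(X + 5.0, X) == pytest.approx(25.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_loop_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 33, 2))
        X = rng.normal(40, 300, shape)
        Y = rng.normal(40, 300, shape)
        assert mae(X, Y) == pytest.approx(_loop_mae(X, Y), rel=1e-10)
        assert mse(X, Y) == pytest.approx(_loop_mse(X, Y), rel=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae(np.zeros((2, 2)), np.zeros((3, 3)))


class TestPsnr:
    def test_closed_form_20db(self):
        Y = np.full((4, 4), 100.0)
        X = Y + 10.0          # MSE = 100 = MAX^2/100
        assert psnr(X, Y) == pytest.approx(20.0, rel=1e-9)

    def test_identical_images_are_infinite(self, rng):
        X = rng.random((4, 4))
        assert psnr(X, X) == math.inf

    def test_halving_mse_adds_3dB(self, rng):
        Y = np.full((100,), 50.0).reshape(10, 10)
        X1 = Y + math.sqrt(2.0)
        X2 = Y + 1.0
        assert psnr(X2, Y) - psnr(X1, Y) \
            == pytest.approx(10 * math.log10(2), rel=1e-9)

    def test_fixed_range_convention(self):
        Y = np.full((4, 4), 100.0)
        X = Y + 28.0
        assert psnr(X, Y, "fixed_range") \
            == pytest.approx(10 * math.log10(2800 ** 2 / 784.0), rel=1e-9)

    def test_matches_skimage(self, rng):
        from skimage.metrics import peak_signal_noise_ratio
        Y = rng.random((16, 16))
        X = np.clip(Y + rng.normal(0, 0.05, Y.shape), 0, 1)
        ours = psnr(X, Y, "fixed_range")
        theirs = peak_signal_noise_ratio(Y, X, data_range=2800.0)
        assert ours == pytest.approx(theirs, rel=1e-10)


class TestSsim:
    def test_self_similarity_is_one(self, rng):
        X = rng.random((32, 32))
        assert ssim(X, X, mode="global") == pytest.approx(1.0)
        assert ssim(X, X, mode="windowed") == pytest.approx(1.0)

    def test_constant_images_reduce_to_luminance_term(self):
        a, b, L = 3.0, 5.0, 4.0
        C1 = (0.01 * L) ** 2
        X = np.full((8, 8), a)
        Y = np.full((8, 8), b)
        expected = (2 * a * b + C1) / (a ** 2 + b ** 2 + C1)
        assert ssim(X, Y, mode="global", dynamic_range=L) \
            == pytest.approx(expected, rel=1e-9)

    def test_anticorrelated_images_negative(self):
        x = np.tile([1.0, -1.0], 32).reshape(8, 8)
        assert ssim(-x, x, mode="global", dynamic_range=2.0) < 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_global_mode_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(0.5, 0.2, (12, 12))
        Y = rng.normal(0.5, 0.2, (12, 12))
        L = 1.0
        ours = ssim(X, Y, mode="global", dynamic_range=L)
        oracle = _loop_ssim_global(X, Y, (0.01 * L) ** 2, (0.03 * L) ** 2)
        assert ours == pytest.approx(oracle, rel=1e-8)

    def test_windowed_mode_matches_skimage(self, rng):
        from skimage.metrics import structural_similarity
        Y = rng.random((48, 48))
        X = np.clip(Y + rng.normal(0, 0.1, Y.shape), 0, 1)
        ours = ssim(X, Y, mode="windowed", dynamic_range=1.0)
        theirs = structural_similarity(X, Y, gaussian_weights=True,
                                       sigma=1.5, use_sample_covariance=False,
                                       data_range=1.0)
        assert ours == pytest.approx(theirs, rel=1e-3)


class TestDice:
    def test_identical_nonempty_masks(self):
        m = np.zeros((1, 4, 4), dtype=int)
        m[0, 1:3, 1:3] = 1
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((1, 4, 4), dtype=int)
        b = np.zeros((1, 4, 4), dtype=int)
        a[0, 0, 0] = 1
        b[0, 3, 3] = 1
        assert dsc(a, b) == 0.0

    def test_hand_counted_half_overlap(self):
        a = np.zeros((1, 4, 4), dtype=int)
        b = np.zeros((1, 4, 4), dtype=int)
        a[0, 0, 0:4] = 1              # |A| = 4
        b[0, 0, 2:4] = 1              # overlap 2
        b[0, 1, 0:2] = 1              # |B| = 4
        assert dsc(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((1, 3, 3), dtype=int)
        assert dsc(z, z) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random((2, 8, 8)) > 0.6).astype(int)
        b = (rng.random((2, 8, 8)) > 0.6).astype(int)
        d1, d2 = dsc(a, b), dsc(b, a)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0


class TestHausdorff:
    def test_identical_masks_zero_distance(self):
        m = np.zeros((1, 8, 8), dtype=int)
        m[0, 2:5, 2:5] = 1
        assert hd95(m, m, spacing=(1, 1, 1)) == 0.0

    def test_two_voxels_five_apart(self):
        a = np.zeros((1, 8, 8), dtype=int)
        b = np.zeros((1, 8, 8), dtype=int)
        a[0, 2, 1] = 1
        b[0, 2, 6] = 1
        assert hd95(a, b, spacing=(1.0, 1.0, 1.0)) == pytest.approx(5.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((1, 8, 8), dtype=int)
        b = np.zeros((1, 8, 8), dtype=int)
        a[0, 2, 1] = 1
        b[0, 2, 6] = 1
        assert hd95(a, b, spacing=(3.0, 1.0, 2.0)) == pytest.approx(10.0)

    def test_symmetric_in_arguments(self, rng):
        a = (rng.random((2, 10, 10)) > 0.7).astype(int)
        b = (rng.random((2, 10, 10)) > 0.7).astype(int)
        if a.any() and b.any():
            assert hd95(a, b, spacing=(1, 1, 1)) \
                == pytest.approx(hd95(b, a, spacing=(1, 1, 1)))

    def test_empty_mask_rejected_with_label(self):
        a = np.zeros((1, 4, 4), dtype=int)
        b = np.zeros((1, 4, 4), dtype=int)
        b[0, 1, 1] = 1
        with pytest.raises(ValueError, match="first"):
            hd95(a, b, spacing=(1, 1, 1))

    def test_growing_gap_grows_distance(self):
        base = np.zeros((1, 8, 32), dtype=int)
        base[0, 3, 2:5] = 1
        near = np.zeros_like(base)
        near[0, 3, 8:11] = 1
        far = np.zeros_like(base)
        far[0, 3, 20:23] = 1
        d_near = hd95(base, near, spacing=(1, 1, 1))
        d_far = hd95(base, far, spacing=(1, 1, 1))
        assert d_far > d_near > 0

    def test_contour_mask_spacing_used(self):
        a = np.zeros((1, 8, 8), dtype=int)
        b = np.zeros((1, 8, 8), dtype=int)
        a[0, 2, 1] = 1
        b[0, 2, 6] = 1
        ma = ContourMask(voxels=a, spacing=(3.0, 0.5, 0.5), label="x")
        mb = ContourMask(voxels=b, spacing=(3.0, 0.5, 0.5), label="x")
        assert hd95(ma, mb) == pytest.approx(2.5)


class TestSummaries:
    def test_reported_mae_decrease(self):
        assert round(relative_change(34.34, 20.25, "decrease")) == 41

    def test_reported_psnr_increase(self):
        assert round(relative_change(34.08, 37.23, "increase"), 1) == 9.2

    def test_no_change_is_zero_percent(self):
        assert relative_change(10.0, 10.0, "decrease") == 0.0

    @pytest.mark.parametrize("dlp,expected", [(485.11, 7.28), (47.15, 0.71)])
    def test_effective_dose_from_dlp(self, dlp, expected):
        assert round(effective_dose(dlp, 0.015), 2) == expected

    def test_zero_dlp_zero_dose(self):
        assert effective_dose(0.0) == 0.0


class TestTTest:
    def test_identical_samples(self):
        r = paired_t_report([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r["t"] == 0.0
        assert r["p"] == pytest.approx(1.0)

    def test_textbook_pooled_variance_oracle(self):
        a = [5.1, 4.9, 5.3, 5.0, 5.2]
        b = [4.2, 4.4, 4.1, 4.5, 4.3]
        na = nb = 5
        va = np.var(a, ddof=1)
        vb = np.var(b, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t_expected = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (2 / 5))
        r = paired_t_report(a, b)
        assert r["t"] == pytest.approx(t_expected, rel=1e-10)

    def test_matches_scipy_equal_variance(self, rng):
        a = rng.normal(10, 2, 12)
        b = rng.normal(11, 2, 15)
        r = paired_t_report(a, b)
        t_sp, p_sp = scipy_stats.ttest_ind(a, b, equal_var=True)
        assert r["t"] == pytest.approx(t_sp, rel=1e-10)
        assert r["p"] == pytest.approx(p_sp, rel=1e-10)

    def test_swapping_samples_negates_t(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 1, 10)
        r1 = paired_t_report(a, b)
        r2 = paired_t_report(b, a)
        assert r1["t"] == pytest.approx(-r2["t"])
        assert r1["p"] == pytest.approx(r2["p"])


class TestVolumeReport:
    def test_per_slice_and_mean_structure(self, rng):
        ref = rng.uniform(-200, 200, (3, 16, 16))
        tst = ref + rng.normal(0, 10, ref.shape)
        rep = evaluate_volumes(ref, tst, label="demo")
        assert len(rep["per_slice"]) == 3
        assert rep["mean"]["mae"] == pytest.approx(
            np.mean([s["mae"] for s in rep["per_slice"]]))
        assert rep["parameters"]["max_convention"] == "reference_max"
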