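"""Spatial-domain features: hand-computed examples, oracles, invariances."""

import math

import numpy as np
import pytest

from dsmri.features import spatial
from dsmri.preprocessing import MaskedSlice, full_mask_slice
from tests.conftest import diagonal_stripes, masked_from_regions


def masked_with_fg_values(values):
    """A slice whose foreground is exactly the given flat values (bg empty)."""
    values = np.asarray(values, dtype=np.float64).reshape(1, -1)
    return full_mask_slice(values)


class TestIntensityStats:
    def test_hand_example(self):
        mean, rng_, var = spatial.intensity_stats(masked_with_fg_values([1, 2, 3, 4]))
        assert mean == pytest.approx(2.5)
        assert rng_ == pytest.approx(3.0)
        assert var == pytest.approx(1.25)

    def test_constant_foreground(self):
        mean, rng_, var = spatial.intensity_stats(masked_with_fg_values([5, 5, 5]))
        assert (mean, rng_, var) == (5.0, 0.0, 0.0)

    def test_shift_covariance(self, rng):
        values = rng.normal(10, 3, size=(6, 6))
        base = spatial.intensity_stats(full_mask_slice(values))
        shifted = spatial.intensity_stats(full_mask_slice(values + 11.5))
        assert shifted[0] == pytest.approx(base[0] + 11.5)
        assert shifted[1] == pytest.approx(base[1])
        assert shifted[2] == pytest.approx(base[2])

    def test_empty_foreground_is_missing(self):
        image = np.zeros((4, 4))
        masked = MaskedSlice(
            image=image,
            fg_mask=np.zeros((4, 4), dtype=bool),
            bg_mask=np.ones((4, 4), dtype=bool),
        )
        assert all(math.isnan(v) for v in spatial.intensity_stats(masked))


class TestCoefficientOfVariation:
    def test_hand_example(self):
        # foreground {2, 4}: population sigma = 1, mean = 3
        assert spatial.coefficient_of_variation(
            masked_with_fg_values([2, 4])
        ) == pytest.approx(1.0 / 3.0)

    def test_constant_foreground_is_zero(self):
        assert spatial.coefficient_of_variation(masked_with_fg_values([7, 7, 7])) == 0.0

    def test_scale_invariance(self, rng):
        values = rng.uniform(1, 5, size=(5, 5))
        base = spatial.coefficient_of_variation(full_mask_slice(values))
        scaled = spatial.coefficient_of_variation(full_mask_slice(values * 4.2))
        assert scaled == pytest.approx(base)

    def test_zero_mean_is_missing(self):
        assert math.isnan(spatial.coefficient_of_variation(masked_with_fg_values([-1, 1])))


class TestCjv:
    def test_hand_example(self):
        # sigma_F=2 (values 8,12), sigma_B=1 (values -1,1), mu_F=10, mu_B=0
        masked = masked_from_regions(
            np.array([[8.0, 12.0], [12.0, 8.0]]), np.array([[-1.0, 1.0], [1.0, -1.0]])
        )
        assert spatial.cjv(masked) == pytest.approx((2 + 1) / 10)

    def test_noiseless_two_level_slice_is_zero(self):
        masked = masked_from_regions(np.full((3, 3), 9.0), np.zeros((3, 3)))
        assert spatial.cjv(masked) == 0.0

    def test_increasing_foreground_spread_increases_cjv(self):
        low = masked_from_regions(np.array([[9.0, 11.0]]), np.array([[0.0, 0.0]]))
        high = masked_from_regions(np.array([[6.0, 14.0]]), np.array([[0.0, 0.0]]))
        assert spatial.cjv(high) > spatial.cjv(low)

    def test_equal_means_is_missing(self):
        masked = masked_from_regions(np.array([[4.0, 6.0]]), np.array([[5.0, 5.0]]))
        assert math.isnan(spatial.cjv(masked))


class TestNoiseMetrics:
    def test_stripe_slice_hand_values(self):
        """Diagonal-stripe regions give every 5x5 patch identical statistics.

        Foreground stripes {4,8,10,12,16}: mean 10, population SD 4.
        Background stripes {-1,1,2,3,5}: mean 2, population SD 2.
        Hence SNR1 = 4/2, SNR2 = 10/2, CNR = (10-2)/2.
        """
        fg = diagonal_stripes((12, 10), [4, 8, 10, 12, 16])
        bg = diagonal_stripes((12, 10), [-1, 1, 2, 3, 5])
        masked = masked_from_regions(fg, bg)
        _, snr1, snr2, cnr = spatial.noise_metrics(masked, seed=3, bg_guard=5)
        assert snr1 == pytest.approx(2.0)
        assert snr2 == pytest.approx(5.0)
        assert cnr == pytest.approx(4.0)

    def test_constant_slice_psnr_is_infinite(self):
        psnr, _, _, _ = spatial.noise_metrics(full_mask_slice(np.full((12, 12), 5.0)))
        assert math.isinf(psnr)

    def test_zero_background_makes_sigma_b_features_missing(self):
        masked = masked_from_regions(
            diagonal_stripes((10, 10), [1, 2, 3, 4, 5]), np.zeros((10, 10))
        )
        _, snr1, snr2, cnr = spatial.noise_metrics(masked, seed=0)
        assert math.isnan(snr1) and math.isnan(snr2) and math.isnan(cnr)

    def test_psnr_decreases_with_noise_level(self):
        """More additive noise on a fixed phantom strictly lowers mean PSNR."""
        base = np.zeros((64, 64))
        base[16:48, 16:48] = 100.0
        mean_psnr = []
        for sd in (2.0, 8.0, 20.0):
            values = []
            for seed in range(10):
                noisy = base + np.random.default_rng(seed).normal(0, sd, base.shape)
                fg = np.zeros_like(base, dtype=bool)
                fg[16:48, 16:48] = True
                masked = MaskedSlice(image=noisy, fg_mask=fg, bg_mask=~fg)
                psnr, _, _, _ = spatial.noise_metrics(masked, seed=seed)
                values.append(psnr)
            mean_psnr.append(np.mean(values))
        assert mean_psnr[0] > mean_psnr[1] > mean_psnr[2]


class TestEfc:
    def test_uniform_slice_attains_one(self):
        assert spatial.efc(full_mask_slice(np.full((9, 13), 4.0))) == pytest.approx(1.0)

    def test_single_nonzero_pixel_is_zero(self):
        image = np.zeros((8, 8))
        image[3, 4] = 42.0
        assert spatial.efc(full_mask_slice(image)) == pytest.approx(0.0)

    def test_matches_double_loop_oracle(self, rng):
        image = rng.uniform(0, 10, size=(8, 8))
        x_max = math.sqrt(sum(image[i, j] ** 2 for i in range(8) for j in range(8)))
        entropy = 0.0
        for i in range(8):
            for j in range(8):
                y = image[i, j] / x_max
                if y > 0:
                    entropy -= y * math.log(y)
        expected = entropy / (math.sqrt(64) * math.log(math.sqrt(64)))
        assert spatial.efc(full_mask_slice(image)) == pytest.approx(expected, rel=1e-9)

    def test_all_zero_slice_is_missing(self):
        assert math.isnan(spatial.efc(full_mask_slice(np.zeros((8, 8)))))

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            image = rng.uniform(0, 1, size=(12, 12)) ** 3
            assert 0.0 <= spatial.efc(full_mask_slice(image)) <= 1.0 + 1e-12


class TestScaleConsistency:
    def test_ratio_features_invariant_to_intensity_scaling(self, rng):
        fg = rng.uniform(5, 10, size=(12, 10))
        bg = rng.uniform(0, 1, size=(12, 10))
        a = masked_from_regions(fg, bg)
        b = masked_from_regions(fg * 3.7, bg * 3.7)
        assert spatial.coefficient_of_variation(b) == pytest.approx(
            spatial.coefficient_of_variation(a)
        )
        assert spatial.cjv(b) == pytest.approx(spatial.cjv(a))
        assert spatial.efc(b) == pytest.approx(spatial.efc(a))
        _, snr1_a, snr2_a, cnr_a = spatial.noise_metrics(a, seed=5, bg_guard=4)
        _, snr1_b, snr2_b, cnr_b = spatial.noise_metrics(b, seed=5, bg_guard=4)
        assert snr1_b == pytest.approx(snr1_a)
        assert snr2_b == pytest.approx(snr2_a)
        assert cnr_b == pytest.approx(cnr_a)
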