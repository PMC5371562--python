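import numpy as np
import pytest
from scipy import stats
from scipy.optimize import curve_fit

from decobubble import (
    DensityBins,
    acclimation_update,
    age_modifier,
    productivity_frequency,
    sample_ahs_count,
    sample_productivity,
    sample_sensitivity,
    sensitivity_frequency,
)
from decobubble.ahs_population import DEFAULT_SENSITIVITY


class TestSensitivityCurve:
    def test_value_at_zero_is_sum_of_coefficients(self):
        assert sensitivity_frequency(0.0) == pytest.approx(0.8001)

    def test_large_argument_reaches_floor(self):
        assert sensitivity_frequency(1e9) == pytest.approx(0.0582, abs=1e-12)

    def test_strictly_decreasing(self):
        grid = np.linspace(0.0, 250.0, 100)
        vals = sensitivity_frequency(grid)
        assert np.all(np.diff(vals) < 0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_frequency(-1.0)


class TestProductivityCurve:
    def test_value_at_one(self):
        assert productivity_frequency(1) == pytest.approx(0.4684, abs=1e-3)

    def test_strictly_decreasing_weights(self):
        vals = productivity_frequency(np.arange(0, 51))
        assert np.all(np.diff(vals) < 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            productivity_frequency(-2)


class TestSensitivitySampler:
    def test_reproducible_under_fixed_seed(self):
        a = sample_sensitivity(np.random.default_rng(7), size=100)
        b = sample_sensitivity(np.random.default_rng(7), size=100)
        assert np.array_equal(a, b)

    def test_support_respected(self, rng):
        draws = sample_sensitivity(rng, b_max=250.0, size=10_000)
        assert draws.min() >= 0.0
        assert draws.max() <= 250.0

    def test_histogram_matches_normalized_curve(self, rng):
        """Chi-square of 1e5 inverse-CDF draws against the analytically
        normalized curve (closed-form bin integrals as the oracle)."""
        b_max, n = 250.0, 100_000
        draws = sample_sensitivity(rng, b_max=b_max, size=n)
        edges = np.linspace(0.0, b_max, 26)
        observed, _ = np.histogram(draws, bins=edges)
        c = DEFAULT_SENSITIVITY

        def mass(lo, hi):
            k = c.rate_per_bubbles_h
            return c.floor * (hi - lo) + c.amplitude / k * (
                np.exp(-k * lo) - np.exp(-k * hi)
            )

        masses = np.array([mass(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])])
        expected = n * masses / masses.sum()
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 1e-3

    def test_parameter_recovery_from_samples(self, rng):
        """Fitting floor + amp * exp(-k b) to a histogram of 1e4 draws
        recovers the decay rate and (normalized) amplitude within 5%."""
        b_max, n = 250.0, 10_000
        draws = sample_sensitivity(rng, b_max=b_max, size=n)
        edges = np.linspace(0.0, b_max, 51)
        counts, _ = np.histogram(draws, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        density = counts / (n * np.diff(edges))

        c = DEFAULT_SENSITIVITY
        k_true = c.rate_per_bubbles_h
        z = c.floor * b_max + c.amplitude / k_true * (1 - np.exp(-k_true * b_max))

        def model(b, floor, amp, k):
            return floor + amp * np.exp(-k * b)

        popt, _ = curve_fit(
            model, centers, density,
            p0=[density[-1], density[0] - density[-1], 0.02],
            sigma=np.sqrt(np.maximum(counts, 1)) / (n * np.diff(edges)),
        )
        assert popt[2] == pytest.approx(k_true, rel=0.05)
        assert popt[1] == pytest.approx(c.amplitude / z, rel=0.05)


class TestProductivitySampler:
    def test_sampled_mean_matches_direct_expectation(self, rng):
        n_max = 50
        draws = sample_productivity(rng, n_max=n_max, size=100_000)
        support = np.arange(1, n_max + 1)
        w = productivity_frequency(support)
        expected_mean = float(np.dot(support, w) / w.sum())
        assert draws.mean() == pytest.approx(expected_mean, rel=0.02)

    def test_support_is_positive_integers(self, rng):
        draws = sample_productivity(rng, n_max=10, size=1000)
        assert draws.min() >= 1 and draws.max() <= 10


class TestAhsCountSampler:
    def test_single_bin_is_deterministic(self, rng):
        bins = DensityBins(weights=(0, 0, 1.0, 0, 0, 0))
        counts = sample_ahs_count(rng, 4.0, bins=bins, size=100)
        assert np.all(counts == 10)  # 2.5 per cm^2 * 4 cm^2

    def test_mean_matches_bin_weighted_expectation(self, rng):
        bins = DensityBins()
        area = 4.0
        counts = sample_ahs_count(rng, area, bins=bins, size=100_000)
        expected = float(
            np.dot(bins.probabilities,
                   np.rint(np.asarray(bins.centers_per_cm2) * area))
        )
        assert counts.mean() == pytest.approx(expected, rel=0.02)

    def test_doubling_area_doubles_expected_count(self, rng):
        a = sample_ahs_count(rng, 2.0, size=50_000).mean()
        b = sample_ahs_count(rng, 4.0, size=50_000).mean()
        assert b == pytest.approx(2.0 * a, rel=0.05)

    def test_nonpositive_area_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_ahs_count(rng, 0.0)


class TestModifiers:
    def test_reference_age_is_identity(self):
        assert age_modifier(20.0, reference_age_years=20.0) == 1.0

    def test_zero_slope_is_flat(self):
        assert age_modifier(77.0, slope_per_year=0.0) == 1.0

    def test_linear_age_scaling(self):
        assert age_modifier(60.0, 20.0, 0.02) == pytest.approx(1.8)
        assert age_modifier(20.0, 20.0, 0.02) == pytest.approx(1.0)

    def test_acclimation_identity_without_detachments(self):
        assert acclimation_update(0.8, 0, 0.5) == (0.8, 0.8)

    def test_acclimation_geometric_decay(self):
        pool, mult = acclimation_update(1.0, 2, 0.5)
        assert pool == pytest.approx(0.25)
        assert mult == pool

    def test_pool_vanishes_with_many_detachments(self):
        pool, _ = acclimation_update(1.0, 10_000, 0.1)
        assert pool == pytest.approx(0.0, abs=1e-12)

    def test_invalid_stripping_fraction(self):
        with pytest.raises(ValueError):
            acclimation_update(1.0, 1, 1.0)
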