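import numpy as np
import pytest
from scipy import integrate, stats

from reaim import mixture
from reaim.circular import AngleSample

TWO_PI = 2.0 * np.pi


def series_i0(x, terms=60):
    """Power-series modified Bessel I0, independent of scipy.special."""
    total, term = 1.0, 1.0
    for k in range(1, terms):
        term *= (x / 2.0) ** 2 / k ** 2
        total += term
    return total


class TestPdf:
    def test_pure_uniform(self):
        p = mixture.MixtureParams(0.0, 0.0, 5.0, 90.0, -90.0)
        assert mixture.mixture_pdf(123.0, p) == pytest.approx(1.0 / TWO_PI)

    def test_kappa_zero_collapses_to_uniform(self):
        p = mixture.MixtureParams(0.6, 0.2, 0.0, 90.0, -90.0)
        for x in (-170.0, 0.0, 90.0):
            assert mixture.mixture_pdf(x, p) == pytest.approx(1.0 / TWO_PI)

    def test_matches_series_oracle(self):
        p = mixture.MixtureParams(0.6, 0.2, 4.0, 90.0, -90.0)
        x = np.pi / 2
        expected = (0.6 * np.exp(4.0 * np.cos(x - np.pi / 2))
                    / (TWO_PI * series_i0(4.0))
                    + 0.2 * np.exp(4.0 * np.cos(x + np.pi / 2))
                    / (TWO_PI * series_i0(4.0))
                    + 0.2 / TWO_PI)
        assert mixture.mixture_pdf(90.0, p) == pytest.approx(expected,
                                                             abs=1e-10)

    def test_integrates_to_one_over_random_parameters(self, rng):
        grid = np.linspace(-180.0, 180.0, 10_001)
        for _ in range(100):
            w1 = rng.uniform(0, 1)
            w2 = rng.uniform(0, 1 - w1)
            p = mixture.MixtureParams(w1, w2, rng.uniform(0, 30),
                                      rng.uniform(1, 180),
                                      rng.uniform(-180, 0))
            dens = mixture.mixture_pdf(grid, p)
            total = integrate.trapezoid(dens, np.deg2rad(grid))
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            mixture.MixtureParams(0.7, 0.5, 1.0, 90.0, -90.0)


class TestNll:
    def test_single_uniform_angle(self):
        p = mixture.MixtureParams(0.0, 0.0, 1.0, 90.0, -90.0)
        nll = mixture.negative_log_likelihood(np.array([42.0]), p)
        assert nll == pytest.approx(np.log(TWO_PI))

    def test_additivity_of_uniform_nll(self):
        p = mixture.MixtureParams(0.0, 0.0, 1.0, 90.0, -90.0)
        n = 37
        nll = mixture.negative_log_likelihood(np.zeros(n) + 5.0, p)
        assert nll == pytest.approx(n * np.log(TWO_PI))

    def test_matches_brute_force_summation(self, rng):
        p = mixture.MixtureParams(0.5, 0.2, 6.0, 75.0, -60.0)
        angles = rng.uniform(-180, 180, 200)
        brute = -sum(np.log(mixture.mixture_pdf(float(a), p))
                     for a in angles)
        assert mixture.negative_log_likelihood(angles, p) == \
            pytest.approx(brute, rel=1e-10)

    def test_empty_sample_rejected(self):
        p = mixture.MixtureParams(0.0, 0.0, 1.0, 90.0, -90.0)
        with pytest.raises(ValueError):
            mixture.negative_log_likelihood(np.array([]), p)


class TestFitBin:
    def test_parameter_recovery(self):
        true = mixture.MixtureParams(0.7, 0.1, 8.0, 75.0, -75.0)
        sample = mixture.sample_from_mixture(true, 2000, seed=11)
        fit = mixture.fit_bin(sample, mixture.FitConfig(n_starts=50, seed=5))
        assert abs(fit.params.mu1_deg - 75.0) <= 3.0
        assert abs(fit.params.w1 - 0.7) <= 0.05
        assert abs(fit.params.kappa - 8.0) / 8.0 <= 0.2

    def test_uniform_sample_gets_tiny_weights(self):
        uniform = mixture.MixtureParams(0.0, 0.0, 1.0, 90.0, -90.0)
        sample = mixture.sample_from_mixture(uniform, 2000, seed=12)
        fit = mixture.fit_bin(sample, mixture.FitConfig(n_starts=50, seed=6))
        assert fit.params.w1 + fit.params.w2 < 0.1

    def test_fixed_mu_pins_means(self):
        true = mixture.MixtureParams(0.6, 0.1, 6.0, 60.0, -120.0)
        sample = mixture.sample_from_mixture(true, 500, seed=3)
        cfg = mixture.FitConfig(n_starts=10, seed=4, variant=mixture.FIXED_MU)
        fit = mixture.fit_bin(sample, cfg)
        assert fit.params.mu1_deg == 90.0
        assert fit.params.mu2_deg == -90.0
        assert fit.aic == pytest.approx(2 * 3 + 2 * fit.nll)

    def test_multi_start_determinism(self):
        true = mixture.MixtureParams(0.5, 0.2, 5.0, 80.0, -80.0)
        sample = mixture.sample_from_mixture(true, 800, seed=9)
        cfg = mixture.FitConfig(n_starts=20, seed=21)
        f1 = mixture.fit_bin(sample, cfg)
        f2 = mixture.fit_bin(sample, cfg)
        assert f1.nll == f2.nll
        assert f1.params == f2.params

    def test_low_n_flagged(self):
        sample = mixture.sample_from_mixture(
            mixture.MixtureParams(0.8, 0.0, 8.0, 90.0, -90.0), 10, seed=1)
        fit = mixture.fit_bin(sample, mixture.FitConfig(n_starts=5, seed=1))
        assert fit.low_n

    def test_nesting_free_at_least_as_good(self, mr_forced_cohort):
        cfg = mixture.FitConfig(n_starts=12, seed=0)
        fits = mixture.fit_all_bins(mr_forced_cohort, config=cfg)
        for ff, fx in zip(fits[mixture.FREE_MU], fits[mixture.FIXED_MU]):
            assert ff.nll <= fx.nll + 1e-3


class TestFitAllBins:
    def test_default_start_is_150ms_bin(self):
        assert mixture.default_start_bin() == 7

    def test_mr_cohort_mu1_ramps(self, mr_forced_cohort):
        cfg = mixture.FitConfig(n_starts=10, seed=0)
        fits = mixture.fit_all_bins(mr_forced_cohort, config=cfg)
        free = fits[mixture.FREE_MU]
        assert [f.bin_index for f in free] == list(range(7, 18))
        mus = np.array([f.params.mu1_deg for f in free])
        slope = np.polyfit(np.arange(len(mus)), mus, 1)[0]
        assert slope > 0

    def test_rc_cohort_mu1_flat_at_solution(self, rc_forced_cohort):
        cfg = mixture.FitConfig(n_starts=10, seed=0)
        fits = mixture.fit_all_bins(rc_forced_cohort, config=cfg,
                                    start_bin=10)
        mus = np.array([f.params.mu1_deg for f in fits[mixture.FREE_MU]])
        assert np.all(np.abs(mus - 90.0) < 10.0)


class TestCompareModels:
    def _mk(self, variant, nll, bin_index):
        k = 5 if variant == mixture.FREE_MU else 3
        return mixture.MixtureFit(params=None, nll=nll, aic=2 * k + 2 * nll,
                                  n=100, bin_index=bin_index, variant=variant,
                                  n_starts_used=1, converged=True)

    def test_equal_nll_penalty_arithmetic(self):
        n_bins = 5
        free = [self._mk(mixture.FREE_MU, 100.0, b) for b in range(n_bins)]
        fixed = [self._mk(mixture.FIXED_MU, 100.0, b) for b in range(n_bins)]
        comp = mixture.compare_models(free, fixed)
        assert comp["preferred"] == mixture.FIXED_MU
        assert comp["delta_aic"] == pytest.approx(2 * 2 * n_bins)

    def test_bin_mismatch_rejected(self):
        free = [self._mk(mixture.FREE_MU, 10.0, 1)]
        fixed = [self._mk(mixture.FIXED_MU, 10.0, 2)]
        with pytest.raises(ValueError):
            mixture.compare_models(free, fixed)


class TestSampling:
    def test_degenerate_concentration(self):
        p = mixture.MixtureParams(1.0, 0.0, 500.0, 90.0, -90.0)
        s = mixture.sample_from_mixture(p, 200, seed=0)
        assert np.all(np.abs(s.angles_deg - 90.0) < 15.0)

    def test_zero_weights_give_uniform(self):
        p = mixture.MixtureParams(0.0, 0.0, 5.0, 90.0, -90.0)
        s = mixture.sample_from_mixture(p, 10_000, seed=1)
        ks = stats.kstest(s.angles_deg, stats.uniform(-180, 360).cdf)
        assert ks.pvalue > 0.01

    def test_component_fractions(self):
        p = mixture.MixtureParams(0.5, 0.3, 50.0, 90.0, -90.0)
        s = mixture.sample_from_mixture(p, 10_000, seed=2)
        near_pos = np.mean(np.abs(s.angles_deg - 90.0) < 40.0)
        near_neg = np.mean(np.abs(s.angles_deg + 90.0) < 40.0)
        # binomial 3-sigma bands around the weights (plus uniform spill ~0.04)
        assert abs(near_pos - 0.5) < 0.06
        assert abs(near_neg - 0.3) < 0.06


def test_round_trip_recovery_over_kappa_range():
    """Moderate-concentration fits invert the generator within tolerance."""
    for i, kappa in enumerate([4.0, 10.0, 16.0]):
        true = mixture.MixtureParams(0.6, 0.15, kappa, 70.0, -90.0)
        sample = mixture.sample_from_mixture(true, 5000, seed=100 + i)
        fit = mixture.fit_bin(sample,
                              mixture.FitConfig(n_starts=30, seed=200 + i))
        assert abs(fit.params.mu1_deg - 70.0) <= 3.0
        assert abs(fit.params.w1 - 0.6) <= 0.05
        assert abs(fit.params.kappa - kappa) / kappa <= 0.2
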