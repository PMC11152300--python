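"""von Mises machinery, Watson U^2, circular correlation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special, stats

from magbird import circular_stats as cs
from magbird.circular_stats import (VonMisesParams, bessel_i, circ_corr,
                                    circ_corr_test, circular_mean, vm_cdf,
                                    vm_mle, vm_pdf, vm_sample, watson_statistic,
                                    watson_u2)
from magbird.errors import (DegenerateDispersionError, TooFewObservationsError,
                            UndefinedMeanError)

TWO_PI = 2 * math.pi


class TestBesselSeries:
    def test_known_values(self):
        assert bessel_i(0, 0.0) == 1.0
        assert bessel_i(1, 0.0) == 0.0
        assert bessel_i(0, 1.0) == pytest.approx(1.2660658777520084, abs=1e-14)

    @pytest.mark.parametrize("p", [0, 1, 3, 7])
    def test_matches_scipy_on_grid(self, p):
        for k in [0.1, 0.5, 2.0, 10.0, 60.0]:
            assert bessel_i(p, k) == pytest.approx(special.iv(p, k), rel=1e-12)


class TestVonMisesPdf:
    def test_uniform_limit(self):
        params = VonMisesParams(0.3, 0.0)
        for th in [0.0, 1.0, 5.0]:
            assert vm_pdf(th, params) == pytest.approx(1 / TWO_PI)

    def test_mode_value_against_series_oracle(self):
        # e / (2 pi I0(1)) from the power-series I0
        want = math.e / (TWO_PI * bessel_i(0, 1.0))
        assert vm_pdf(1.0, VonMisesParams(1.0, 1.0)) == pytest.approx(want, rel=1e-14)

    @given(st.floats(0, TWO_PI), st.floats(0.01, 50), st.floats(-3, 3))
    @settings(max_examples=40, deadline=None)
    def test_symmetric_about_mean(self, mu, kappa, x):
        p = VonMisesParams(mu, kappa)
        assert vm_pdf(mu + x, p) == pytest.approx(vm_pdf(mu - x, p), rel=1e-12)

    def test_matches_scipy_distribution(self):
        p = VonMisesParams(1.2, 3.5)
        th = np.linspace(0, TWO_PI, 17)
        np.testing.assert_allclose(vm_pdf(th, p),
                                   stats.vonmises.pdf(th, 3.5, loc=1.2),
                                   rtol=1e-12)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            VonMisesParams(0.0, -1.0)


class TestVonMisesCdf:
    def test_normalization_endpoints(self):
        for kappa in [0.0, 0.7, 5.0, 40.0]:
            p = VonMisesParams(2.0, kappa)
            assert vm_cdf(0.0, p) == 0.0
            assert vm_cdf(TWO_PI, p) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_limit_is_linear(self):
        p = VonMisesParams(1.0, 0.0)
        th = np.linspace(0, TWO_PI, 9)
        np.testing.assert_allclose(vm_cdf(th, p), th / TWO_PI)

    def test_derivative_matches_pdf(self, rng):
        p = VonMisesParams(2.5, 3.0)
        h = 1e-6
        for th in rng.uniform(h, TWO_PI - h, 50):
            deriv = (vm_cdf(th + h, p) - vm_cdf(th - h, p)) / (2 * h)
            assert deriv == pytest.approx(vm_pdf(th, p), rel=1e-5, abs=1e-8)

    def test_matches_numerical_integral(self):
        p = VonMisesParams(4.0, 8.0)
        for th in [0.5, 2.0, 4.5, 6.0]:
            want, _ = integrate.quad(lambda x: vm_pdf(x, p), 0, th,
                                     limit=200)
            assert vm_cdf(th, p) == pytest.approx(want, abs=1e-10)

    @given(st.floats(0, TWO_PI), st.floats(0, 80))
    @settings(max_examples=40, deadline=None)
    def test_nondecreasing(self, mu, kappa):
        p = VonMisesParams(mu, kappa)
        vals = vm_cdf(np.linspace(0, TWO_PI, 200), p)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            vm_cdf(-0.5, VonMisesParams(0, 1))


class TestVonMisesSampler:
    def test_reproducible_with_seed(self):
        p = VonMisesParams(1.0, 2.0)
        np.testing.assert_array_equal(vm_sample(100, p, seed=7),
                                      vm_sample(100, p, seed=7))

    def test_values_wrapped(self):
        x = vm_sample(1000, VonMisesParams(6.0, 0.5), seed=0)
        assert np.all((x >= 0) & (x < TWO_PI))

    def test_circular_mean_converges(self):
        x = vm_sample(10_000, VonMisesParams(1.0, 4.0), seed=11)
        assert abs(circular_mean(x) - 1.0) < 0.05

    def test_uniform_kappa_passes_watson_at_nominal_rate(self):
        rejections = 0
        reps = 200
        for i in range(reps):
            x = vm_sample(50, VonMisesParams(0.0, 0.0), seed=1000 + i)
            rejections += watson_u2(x, "uniformity", n_boot=200, seed=i).reject
        # binomial(200, 0.05): 3 sigma is about +-0.046
        assert 0.0 <= rejections / reps <= 0.12


class TestCircularMean:
    def test_simple_cases(self):
        assert circular_mean([0.0, 0.0, 0.0]) == 0.0
        assert circular_mean([math.pi / 2] * 2) == pytest.approx(math.pi / 2)

    def test_antipodal_pair_is_undefined(self):
        with pytest.raises(UndefinedMeanError):
            circular_mean([0.0, math.pi])

    def test_wraps_through_zero(self):
        assert circular_mean([0.1, TWO_PI - 0.1]) == pytest.approx(0.0, abs=1e-12)


class TestVonMisesMle:
    def test_uniform_grid_has_no_mean_direction(self):
        grid = np.arange(36) * TWO_PI / 36
        with pytest.raises(UndefinedMeanError):
            vm_mle(grid)

    def test_identical_angles_hit_concentration_cap(self):
        fit = vm_mle(np.full(20, 1.3))
        assert fit.kappa == cs.KAPPA_CAP
        assert fit.mu == pytest.approx(1.3)

    def test_solves_bessel_ratio_equation(self, rng):
        x = vm_sample(500, VonMisesParams(2.0, 3.0), seed=5)
        fit = vm_mle(x)
        rbar = cs.mean_resultant_length(x)
        assert special.i1e(fit.kappa) / special.i0e(fit.kappa) == pytest.approx(
            rbar, abs=1e-9)

    def test_single_sample_recovery(self):
        x = vm_sample(2000, VonMisesParams(1.0, 2.0), seed=3)
        fit = vm_mle(x)
        assert abs(fit.mu - 1.0) < 0.1
        assert abs(fit.kappa - 2.0) / 2.0 < 0.15

    def test_batch_mle_matches_scalar(self, rng):
        samples = rng.vonmises(1.0, 2.5, size=(5, 300)) % TWO_PI
        mu_b, kappa_b = cs._vm_mle_batch(samples)
        for i in range(5):
            fit = vm_mle(samples[i])
            assert mu_b[i] == pytest.approx(fit.mu, abs=1e-9)
            assert kappa_b[i] == pytest.approx(fit.kappa, rel=1e-8)


class TestWatson:
    def test_midpoint_identity(self):
        u = (np.arange(1, 11) - 0.5) / 10
        assert watson_statistic(u) == pytest.approx(1 / 120, abs=1e-15)

    def test_lower_bound_with_duplicated_observations(self):
        u = np.repeat(np.linspace(0.05, 0.95, 10), 2)
        w = watson_statistic(u)
        assert math.isfinite(w)
        assert w >= 1 / (12 * u.size) - 1e-15

    def test_reordering_sample_does_not_change_statistic(self, rng):
        x = vm_sample(40, VonMisesParams(1, 1), seed=2)
        r1 = watson_u2(x, "uniformity", n_boot=50, seed=9)
        r2 = watson_u2(rng.permutation(x), "uniformity", n_boot=50, seed=9)
        assert r1.u2 == pytest.approx(r2.u2, abs=1e-14)

    def test_uniformity_statistic_rotation_invariant(self, rng):
        x = vm_sample(60, VonMisesParams(2, 2), seed=4)
        base = watson_u2(x, "uniformity", n_boot=50, seed=0).u2
        for c in rng.uniform(0, TWO_PI, 5):
            rotated = (x + c) % TWO_PI
            assert watson_u2(rotated, "uniformity", n_boot=50,
                             seed=0).u2 == pytest.approx(base, abs=1e-10)

    def test_accepts_von_mises_data_against_von_mises_null(self):
        x = vm_sample(200, VonMisesParams(1.0, 2.0), seed=8)
        res = watson_u2(x, "vonmises_estimated", n_boot=300, seed=8)
        assert not res.reject
        assert res.reject == (res.u2 > res.critical_value)

    def test_rejects_bimodal_data_against_von_mises_null(self):
        half = vm_sample(100, VonMisesParams(0.5, 8.0), seed=1)
        other = vm_sample(100, VonMisesParams(0.5 + math.pi, 8.0), seed=2)
        res = watson_u2(np.concatenate([half, other]), "vonmises_estimated",
                        n_boot=300, seed=3)
        assert res.reject

    def test_small_sample_rejected(self):
        with pytest.raises(TooFewObservationsError):
            watson_u2(np.ones(7), "uniformity")


class TestCircCorr:
    def test_identity_gives_one(self, rng):
        x = vm_sample(50, VonMisesParams(1, 2), seed=0)
        assert circ_corr(x, x) == pytest.approx(1.0)

    def test_reflection_gives_minus_one(self):
        x = vm_sample(50, VonMisesParams(1, 2), seed=0)
        assert circ_corr(x, (TWO_PI - x) % TWO_PI) == pytest.approx(-1.0)

    def test_matches_high_precision_oracle(self):
        # direct evaluation of the sine-moment formula at 40 digits
        r = circ_corr([0.1, 1.2, 2.3, 4.0], [0.3, 1.0, 2.5, 3.9])
        assert r == pytest.approx(0.9872038584050816, abs=1e-14)

    def test_invariant_under_independent_rotations(self, rng):
        x = vm_sample(100, VonMisesParams(1, 2), seed=1)
        y = vm_sample(100, VonMisesParams(4, 3), seed=2)
        base = circ_corr(x, y)
        for _ in range(5):
            cx, cy = rng.uniform(0, TWO_PI, 2)
            assert abs(circ_corr((x + cx) % TWO_PI, (y + cy) % TWO_PI)
                       - base) < 1e-12

    def test_degenerate_dispersion_raises(self):
        x = vm_sample(30, VonMisesParams(1, 2), seed=1)
        with pytest.raises(DegenerateDispersionError):
            circ_corr(x, np.full(30, 0.7))


class TestCircCorrTest:
    def test_perfect_dependence_is_significant(self):
        x = vm_sample(100, VonMisesParams(0, 2), seed=6)
        res = circ_corr_test(x, x)
        assert res.p_value < 1e-10
        assert res.z_stat > 5
        assert res.reject

    def test_power_monotone_in_coupling(self):
        couplings = [0.0, 0.2, 0.5]
        reps = 150
        rates = []
        for c in couplings:
            rej = 0
            for i in range(reps):  # paired seeds across couplings
                rng_i = np.random.default_rng(10_000 + i)
                x = rng_i.vonmises(0.0, 2.0, 200) % TWO_PI
                noise = rng_i.vonmises(0.0, 2.0, 200)
                y = (c * x + noise) % TWO_PI
                rej += circ_corr_test(y, x).reject
            rates.append(rej / reps)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]

    def test_small_sample_warns_then_errors(self):
        x = vm_sample(10, VonMisesParams(0, 2), seed=1)
        y = vm_sample(10, VonMisesParams(1, 2), seed=2)
        with pytest.warns(UserWarning, match="n < 25"):
            circ_corr_test(x, y)
        with pytest.raises(TooFewObservationsError):
            circ_corr_test(x[:3], y[:3])
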