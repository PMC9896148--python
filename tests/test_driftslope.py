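import numpy as np
import pytest

from driftscan import driftslope
from driftscan.driftslope import (DriftDiffusionParams, EstimationError,
                                  MCMCConfig, PriorSpec)
from driftscan.preprocess import WindowSpec
from tests.conftest import ou_window

DT = 0.02


def params(t0=0.0, t1=0.0, t2=0.0, t3=0.0, s=1.0):
    return DriftDiffusionParams(t0, t1, t2, t3, s)


class TestPolynomialDrift:
    def test_linear(self):
        assert driftslope.polynomial_drift(2.0, params(t1=-1.0)) == -2.0

    def test_zero(self):
        assert driftslope.polynomial_drift(5.0, params()) == 0.0

    def test_cubic(self):
        assert driftslope.polynomial_drift(2.0, params(1.0, 1.0, 1.0, 1.0)) == 15.0

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            params(s=0.0)


class TestLogLikelihood:
    def test_single_transition_closed_form(self):
        p = params(t0=0.5, t1=-1.0, s=2.0)
        x = np.array([1.0, 1.3])
        mu = x[0] + driftslope.polynomial_drift(x[0], p) * DT
        var = p.sigma_diff ** 2 * DT
        expected = -0.5 * (x[1] - mu) ** 2 / var - 0.5 * np.log(2 * np.pi * var)
        assert driftslope.log_likelihood(x, p, DT) == pytest.approx(expected, rel=1e-12)

    def test_translation_with_recentred_intercept(self):
        x = ou_window(-1.0, 1.0, 500, DT, seed=0)
        theta1, c = -1.0, 3.7
        l1 = driftslope.log_likelihood(x, params(t0=0.0, t1=theta1), DT)
        # shifting the data by c while re-centring theta0 by -theta1*c leaves
        # the linear drift residuals unchanged
        l2 = driftslope.log_likelihood(x + c, params(t0=-theta1 * c, t1=theta1), DT)
        assert l1 == pytest.approx(l2, rel=1e-10)

    def test_truth_beats_perturbation(self):
        x = ou_window(-1.0, 1.0, 4000, DT, seed=1)
        truth = params(t1=-1.0)
        assert driftslope.log_likelihood(x, truth, DT) > \
            driftslope.log_likelihood(x, params(t1=-2.0), DT)
        assert driftslope.log_likelihood(x, truth, DT) > \
            driftslope.log_likelihood(x, params(t1=0.0), DT)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            driftslope.log_likelihood([1.0], params(), DT)


class TestLogPrior:
    def test_origin_value(self):
        spec = PriorSpec()
        lp = driftslope.log_prior(params(s=1.0), spec)
        # at theta1 = 0 the straight-line prior contributes log(1/(2 pi))
        gauss = sum(-0.5 * np.log(2 * np.pi * sd ** 2) for sd in (4.0, 8.0))
        assert lp == pytest.approx(-np.log(2 * np.pi) + gauss, rel=1e-12)

    def test_outside_support(self):
        spec = PriorSpec()
        assert driftslope.log_prior(params(t0=60.0), spec) == -np.inf
        assert driftslope.log_prior(params(s=55.0), spec) == -np.inf

    def test_theta1_ratio(self):
        spec = PriorSpec()
        r = driftslope.log_prior(params(t1=0.0), spec) - \
            driftslope.log_prior(params(t1=1.0), spec)
        assert np.exp(r) == pytest.approx(2 ** 1.5, rel=1e-12)

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(2)
        spec = PriorSpec()
        x = ou_window(-1.0, 1.0, 300, DT, seed=3)
        x0, dx = x[:-1], np.diff(x)
        for _ in range(20):
            vec = np.concatenate([rng.uniform(-5, 5, 4), rng.uniform(0.1, 5, 1)])
            p = DriftDiffusionParams.from_vector(vec)
            expected = driftslope.log_prior(p, spec) + \
                driftslope.log_likelihood(x, p, DT)
            got = driftslope._log_posterior_batch(vec[None, :], x0, dx, DT, spec)[0]
            assert got == pytest.approx(expected, rel=1e-10)


class TestFitWindow:
    def test_determinism(self, fast_mcmc):
        x = ou_window(-1.0, 1.0, 300, DT, seed=4)
        a = driftslope.fit_window(x, DT, config=fast_mcmc, seed=11)
        b = driftslope.fit_window(x, DT, config=fast_mcmc, seed=11)
        assert np.array_equal(a.draws, b.draws)

    def test_constant_window_fails(self, fast_mcmc):
        with pytest.raises(EstimationError):
            driftslope.fit_window(np.ones(100), DT, config=fast_mcmc)

    def test_short_window_rejected(self, fast_mcmc):
        with pytest.raises(ValueError):
            driftslope.fit_window(np.zeros(20), DT, config=fast_mcmc)

    def test_draws_respect_prior_support(self, fast_mcmc):
        x = ou_window(-1.0, 1.0, 300, DT, seed=5)
        s = driftslope.fit_window(x, DT, config=fast_mcmc, seed=12)
        spec = PriorSpec()
        assert np.all(s.draws[:, 0] > spec.theta01_box[0])
        assert np.all(s.draws[:, 0] < spec.theta01_box[1])
        assert np.all(s.draws[:, 4] > 0)
        assert np.all(s.draws[:, 4] < spec.sigma_range[1])

    def test_recovery_single_seed(self):
        x = ou_window(-1.0, 1.0, 2000, DT, seed=6)
        s = driftslope.fit_window(x, DT, config=MCMCConfig(walkers=24, steps=600,
                                                           burn=200, thin=2), seed=13)
        est = driftslope.slope_posterior_summary(s)
        lo, hi = est.band_98
        assert lo <= -1.0 <= hi


class TestSlope:
    def test_linear_only(self):
        assert driftslope.slope_from_params(params(t1=-2.0), x_star=5.0) == -2.0

    def test_x_star_zero(self):
        assert driftslope.slope_from_params(params(t1=3.0, t2=1.0, t3=1.0), 0.0) == 3.0

    def test_full_formula(self):
        assert driftslope.slope_from_params(params(0.0, 1.0, 1.0, 1.0), 2.0) == 17.0

    def test_array_draws(self):
        draws = np.array([[0.0, 1.0, 1.0, 1.0, 1.0],
                          [0.0, 2.0, 0.0, 0.0, 1.0]])
        z = driftslope.slope_from_params(draws, 2.0)
        assert np.allclose(z, [17.0, 2.0])


class TestSummary:
    def _sample(self, draws):
        from driftscan.driftslope import PosteriorSample
        return PosteriorSample(draws=draws, acceptance_fraction=0.5, seed=0, x_star=0.0)

    def test_degenerate_draws(self):
        draws = np.tile([0.0, -1.5, 0.0, 0.0, 1.0], (100, 1))
        est = driftslope.slope_posterior_summary(self._sample(draws))
        assert est.zeta_map == -1.5
        assert est.band_68 == (-1.5, -1.5) and est.band_98 == (-1.5, -1.5)

    def test_band_ordering(self):
        rng = np.random.default_rng(7)
        draws = np.zeros((5000, 5))
        draws[:, 1] = rng.standard_normal(5000)
        est = driftslope.slope_posterior_summary(self._sample(draws))
        q16, q84 = est.band_68
        q01, q99 = est.band_98
        assert q01 <= q16 <= q84 <= q99

    def test_kde_mode_near_histogram_argmax(self):
        rng = np.random.default_rng(8)
        draws = np.zeros((20000, 5))
        draws[:, 1] = rng.normal(loc=-2.0, scale=0.5, size=20000)
        est = driftslope.slope_posterior_summary(self._sample(draws))
        counts, edges = np.histogram(draws[:, 1], bins=50)
        hist_mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        bin_width = edges[1] - edges[0]
        assert abs(est.zeta_map - hist_mode) <= bin_width


class TestRolling:
    def test_count_and_alignment(self, fast_mcmc):
        x = ou_window(-1.0, 1.0, 450, DT, seed=9)
        spec = WindowSpec(size=150, shift=150)
        ests = driftslope.rolling_drift_slope(x, DT, spec=spec,
                                              mcmc_config=fast_mcmc, seed=1)
        assert len(ests) == 3
        df = driftslope.slope_table(ests)
        assert list(df.columns) == ["window_end_time", "zeta_map", "q16", "q84",
                                    "q01", "q99", "x_star"]

    def test_failed_window_is_missing(self, fast_mcmc):
        x = np.concatenate([np.zeros(150), ou_window(-1.0, 1.0, 150, DT, seed=10)])
        ests = driftslope.rolling_drift_slope(x, DT, spec=WindowSpec(150, 150),
                                              mcmc_config=fast_mcmc, seed=2)
        assert ests[0] is None and ests[1] is not None
        df = driftslope.slope_table(ests)
        assert np.isnan(df["zeta_map"].iloc[0])
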