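"""Prior/posterior densities, the closed-form bandwidth, and the rate estimate."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.special import gammaln

from baks import (
    BAKSConfig,
    RenewalModelParams,
    RateParams,
    SpikeTrain,
    adaptive_bandwidth,
    default_beta,
    estimate_rate,
    generate_spike_train,
    integrated_squared_error,
    mise_experiment,
    posterior_density,
    prior_density,
    prior_moments,
    time_grid,
)
from baks.evaluation import ScenarioSpec


def _integrate_density(f, scale):
    """Piecewise adaptive quadrature of a density of h over (0, inf)."""
    pieces = [(0.0, 0.1 * scale), (0.1 * scale, scale), (scale, 10 * scale),
              (10 * scale, 100 * scale), (100 * scale, np.inf)]
    return sum(quad(f, a, b, limit=200)[0] for a, b in pieces)


class TestDefaultBeta:
    @pytest.mark.parametrize("n, expected", [(1, 1.0), (32, 16.0), (100, 100 ** 0.8)])
    def test_power_rule(self, n, expected):
        assert default_beta(n) == pytest.approx(expected, rel=1e-12)

    def test_zero_spikes_is_an_error(self):
        with pytest.raises(ValueError):
            default_beta(0)


class TestPrior:
    def test_normalization(self):
        total = _integrate_density(lambda h: prior_density(h, 4.0, 1.0), 1.0)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_change_of_variables_against_gamma_on_precision(self):
        """pi(h) must equal the Gamma density of sigma = 1/h^2 times |dsigma/dh|."""
        rng = np.random.default_rng(0)
        alpha, beta = 3.0, 2.0
        h = rng.uniform(0.05, 3.0, size=100)
        sigma = 1.0 / (h * h)
        expected = stats.gamma(a=alpha, scale=beta).pdf(sigma) * (2.0 / h**3)
        assert np.allclose(prior_density(h, alpha, beta), expected, rtol=1e-10)

    def test_vanishes_at_extremes(self):
        assert prior_density(1e-8, 4.0, 1.0) == pytest.approx(0.0, abs=1e-30)
        assert prior_density(1e8, 4.0, 1.0) == pytest.approx(0.0, abs=1e-30)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            prior_density(-0.1, 4.0, 1.0)


class TestPriorMoments:
    def test_closed_form_value(self):
        mean, var = prior_moments(4.0, 1.0)
        assert mean == pytest.approx(math.gamma(3.5) / math.gamma(4.0), rel=1e-12)
        assert var > 0

    def test_beta_scaling(self):
        m1, _ = prior_moments(4.0, 1.0)
        m4, _ = prior_moments(4.0, 4.0)
        assert m4 == pytest.approx(m1 / 2.0, rel=1e-12)

    def test_against_monte_carlo(self):
        rng = np.random.default_rng(1)
        alpha, beta = 4.0, 2.0
        h = 1.0 / np.sqrt(rng.gamma(alpha, beta, size=1_000_000))
        mean, var = prior_moments(alpha, beta)
        assert abs(h.mean() - mean) < 3 * h.std() / 1000.0
        assert h.var() == pytest.approx(var, rel=0.02)

    def test_alpha_at_most_one_diverges(self):
        with pytest.raises(ValueError):
            prior_moments(1.0, 1.0)


class TestPosterior:
    def test_single_spike_normalization(self):
        spikes = SpikeTrain([0.7], 2.0)
        f = lambda h: posterior_density(h, 1.1, spikes, 4.0, 1.0)
        assert _integrate_density(f, 1.0) == pytest.approx(1.0, abs=1e-8)

    def test_mass_shifts_to_larger_h_away_from_the_spike(self):
        """With one spike, the posterior-mean bandwidth grows with |t - t1|."""
        spikes = SpikeTrain([1.0], 4.0)
        ts = np.array([1.0, 1.5, 2.0, 3.0])
        h = adaptive_bandwidth(spikes, 4.0, 1.0, ts).h_values
        assert np.all(np.diff(h) > 0)

    def test_bayes_rule_oracle(self):
        """Pointwise likelihood x prior / numeric marginal reproduces the
        closed-form posterior at arbitrary h."""
        rng = np.random.default_rng(2)
        spikes = SpikeTrain(np.sort(rng.uniform(0.01, 2.0, size=50)), 2.0)
        alpha, beta, t = 4.0, default_beta(50), 0.9

        def likelihood(h):
            return np.mean(
                np.exp(-((t - spikes.times) ** 2) / (2 * h * h))
                / (np.sqrt(2 * np.pi) * h)
            )

        unnorm = lambda h: likelihood(h) * prior_density(h, alpha, beta)
        marginal = _integrate_density(unnorm, 0.3)
        hs = np.exp(rng.uniform(np.log(0.01), np.log(2.0), size=20))
        oracle = np.array([unnorm(h) / marginal for h in hs])
        ours = posterior_density(hs, t, spikes, alpha, beta)
        assert np.allclose(ours, oracle, rtol=1e-6)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            posterior_density(0.5, 1.0, SpikeTrain([], 2.0), 4.0, 1.0)


class TestAdaptiveBandwidth:
    def test_single_spike_closed_form(self):
        spikes = SpikeTrain([1.0], 2.0)
        h = adaptive_bandwidth(spikes, 4.0, 1.0, np.array([1.0])).h_values[0]
        assert h == pytest.approx(math.gamma(4.0) / math.gamma(4.5), abs=1e-12)

    def test_single_spike_scales_with_distance(self):
        """One spike: Eq-by-hand ratio reduces to
        sqrt((t-t1)^2/2 + 1/beta) * Gamma(a)/Gamma(a+1/2)."""
        spikes = SpikeTrain([1.0], 4.0)
        t = 1.0 + np.sqrt(2.0)
        h = adaptive_bandwidth(spikes, 4.0, 1.0, np.array([t])).h_values[0]
        expected = math.gamma(4.0) / math.gamma(4.5) * np.sqrt(2.0)
        assert h == pytest.approx(expected, abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0.01, 2.0, size=40))
        grid = np.linspace(0, 2, 101)
        h0 = adaptive_bandwidth(SpikeTrain(times, 2.0), 4.0, 19.0, grid).h_values
        h1 = adaptive_bandwidth(
            SpikeTrain(times + 5.0, 7.0), 4.0, 19.0, grid + 5.0
        ).h_values
        assert np.allclose(h0, h1, rtol=1e-12)

    def test_posterior_mean_quadrature_oracle(self):
        """Closed form equals int h pi(h|rho) dh by quadrature."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = rng.integers(3, 40)
            spikes = SpikeTrain(np.sort(rng.uniform(0.01, 2.0, size=n)), 2.0)
            alpha = rng.uniform(2.0, 8.0)
            beta = rng.uniform(0.5, 30.0)
            t = rng.uniform(0.0, 2.0)
            closed = adaptive_bandwidth(spikes, alpha, beta, np.array([t])).h_values[0]
            integrand = lambda h: h * posterior_density(h, t, spikes, alpha, beta)
            numeric = _integrate_density(integrand, closed)
            assert numeric == pytest.approx(closed, rel=1e-6)

    def test_smaller_bandwidth_in_denser_regions(self):
        rng = np.random.default_rng(5)
        times = np.sort(
            np.concatenate([rng.uniform(0.0, 1.0, 50), rng.uniform(1.0, 2.0, 5)])
        )
        spikes = SpikeTrain(times, 2.0)
        grid = np.linspace(0, 2, 401)
        h = adaptive_bandwidth(spikes, 4.0, default_beta(55), grid).h_values
        dense = h[(grid >= 0.2) & (grid <= 0.8)].mean()
        sparse = h[(grid >= 1.2) & (grid <= 1.8)].mean()
        assert dense < sparse

    def test_log_domain_matches_naive_evaluation(self):
        """Where the naive power sums stay in range, both forms agree."""
        rng = np.random.default_rng(6)
        spikes = SpikeTrain(np.sort(rng.uniform(0.01, 2.0, size=20)), 2.0)
        alpha, beta = 3.0, 5.0
        grid = np.linspace(0, 2, 101)
        h = adaptive_bandwidth(spikes, alpha, beta, grid).h_values
        c = 0.5 * (grid[:, None] - spikes.times) ** 2 + 1.0 / beta
        naive = (
            math.gamma(alpha)
            / math.gamma(alpha + 0.5)
            * (c ** -alpha).sum(axis=1)
            / (c ** -(alpha + 0.5)).sum(axis=1)
        )
        assert np.allclose(h, naive, rtol=1e-10)

    def test_extreme_alpha_remains_finite(self):
        spikes = SpikeTrain([0.01, 1.99], 2.0)
        grid = np.linspace(0, 2, 201)
        h = adaptive_bandwidth(spikes, 10.0, default_beta(2), grid).h_values
        assert np.all(np.isfinite(h)) and np.all(h > 0)


class TestEstimateRate:
    def test_single_spike_peak_value(self):
        spikes = SpikeTrain([1.0], 2.0)
        curve = estimate_rate(spikes, BAKSConfig(alpha=4.0, beta=1.0), time_grid(2.0))
        h = math.gamma(4.0) / math.gamma(4.5)
        assert curve.values[1000] == pytest.approx(1 / (np.sqrt(2 * np.pi) * h), abs=1e-10)

    def test_translation_invariance_of_curve(self):
        rng = np.random.default_rng(7)
        times = np.sort(rng.uniform(0.01, 2.0, size=30))
        grid = np.linspace(0, 2, 201)
        c0 = estimate_rate(SpikeTrain(times, 2.0), BAKSConfig(), grid)
        c1 = estimate_rate(SpikeTrain(times + 3.0, 5.0), BAKSConfig(), grid + 3.0)
        assert np.allclose(c0.values, c1.values, rtol=1e-12)

    def test_approximate_mass_conservation(self):
        """Integrated estimate over an extended window recovers ~n spikes."""
        rate = RateParams("sine", 50.0, 0.0, 1.0)
        model = RenewalModelParams("IG", 1.0, scale=1.0)
        train = generate_spike_train(rate, model, 2.0, np.random.default_rng(8))
        wide = np.linspace(-1.0, 3.0, 4001)
        curve = estimate_rate(train, BAKSConfig(), wide)
        mass = np.trapezoid(curve.values, wide)
        assert mass == pytest.approx(train.n, rel=0.05)

    def test_empty_train_handling(self):
        empty = SpikeTrain([], 2.0)
        grid = time_grid(2.0, 1e-2)
        with pytest.raises(ValueError, match="allow_empty"):
            estimate_rate(empty, BAKSConfig(), grid)
        curve = estimate_rate(empty, BAKSConfig(), grid, allow_empty=True)
        assert np.all(curve.values == 0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BAKSConfig(alpha=-1.0)
        with pytest.raises(ValueError):
            BAKSConfig(alpha=4.0, beta="n^2")
        assert BAKSConfig(alpha=4.0, beta="auto").resolve_beta(32) == pytest.approx(16.0)
        assert BAKSConfig(alpha=4.0, beta=2.5).resolve_beta(32) == 2.5

    def test_relative_error_shrinks_with_spike_count(self):
        """Consistency: with a 10x higher homogeneous rate (hence ~10x the
        spikes), the median *relative* ISE, ISE/(rate^2 * T), decreases."""
        model = RenewalModelParams("IG", 1.0, scale=1.0)
        rel = {}
        for rate_hz in (5.0, 50.0):
            scen = ScenarioSpec(
                label=f"const-{rate_hz}",
                rate=RateParams("sine", rate_hz, 0.0, 1.0),
                model=model,
                duration=2.0,
                repetitions=20,
            )
            res = mise_experiment(scen, BAKSConfig(), seed=3)
            rel[rate_hz] = np.median(res.ise_per_repetition) / (rate_hz**2 * 2.0)
        assert rel[50.0] < rel[5.0]
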