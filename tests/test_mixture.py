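import numpy as np
import pytest

from foodseg import (
    FitConfig,
    Mixture1D,
    bayes_threshold,
    fit_em,
    kurtosis_threshold,
    message_length,
    select_model,
)


def bimodal_sample(rng, n=20000, mu=(0.3, 0.7), sigma=(0.02, 0.02), w=0.5):
    n1 = int(n * w)
    return np.concatenate([
        rng.normal(mu[0], sigma[0], n1),
        rng.normal(mu[1], sigma[1], n - n1),
    ])


def grid_crossover(model, n_points=1_000_001):
    """Brute-force posterior-crossover search between the two means."""
    (m1, m2), (v1, v2), (p1, p2) = model.means, model.variances, model.weights
    grid = np.linspace(m1, m2, n_points)
    d1 = p1 * np.exp(-0.5 * (grid - m1) ** 2 / v1) / np.sqrt(2 * np.pi * v1)
    d2 = p2 * np.exp(-0.5 * (grid - m2) ** 2 / v2) / np.sqrt(2 * np.pi * v2)
    return float(grid[np.argmin(np.abs(d1 - d2))])


def make_mixture(weights, means, variances, n=10000.0, loglik=0.0):
    return Mixture1D(
        weights=np.asarray(weights, float), means=np.asarray(means, float),
        variances=np.asarray(variances, float), C=len(means),
        loglik=loglik, n=n, converged=True,
    )


class TestEM:
    def test_single_component_closed_form(self, rng):
        v = rng.normal(0.5, 0.1, 5000)
        counts, edges = np.histogram(v, bins=256)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mix = fit_em(v, 1)
        mu = np.average(centers, weights=counts)
        var = np.average((centers - mu) ** 2, weights=counts)
        assert mix.means[0] == pytest.approx(mu, abs=1e-9)
        assert mix.variances[0] == pytest.approx(var, rel=1e-6)
        assert mix.weights[0] == 1.0

    def test_parameter_recovery_bimodal(self, rng):
        v = bimodal_sample(rng)
        mix = fit_em(v, 2)
        assert mix.means[0] == pytest.approx(0.3, abs=0.01)
        assert mix.means[1] == pytest.approx(0.7, abs=0.01)
        assert mix.weights[0] == pytest.approx(0.5, abs=0.03)

    def test_loglik_trace_monotone(self, rng):
        for _ in range(5):
            v = bimodal_sample(rng, n=2000, sigma=(0.05, 0.08), w=0.3)
            mix = fit_em(v, 2)
            diffs = np.diff(mix.loglik_trace)
            assert (diffs >= -1e-8 * np.abs(mix.loglik)).all()

    def test_deterministic(self, rng):
        v = bimodal_sample(rng)
        a, b = fit_em(v, 2), fit_em(v, 2)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_components_sorted_by_mean(self, rng):
        v = bimodal_sample(rng, w=0.8)
        mix = fit_em(v, 2)
        assert mix.means[0] < mix.means[1]
        assert mix.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_data(self):
        mix = fit_em(np.full(500, 0.42), 1)
        assert mix.degenerate
        assert mix.means[0] == pytest.approx(0.42)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least"):
            fit_em(np.arange(15.0), 2)

    def test_accepts_precomputed_histogram(self, rng):
        v = rng.normal(0.5, 0.05, 10000)
        counts, edges = np.histogram(v, bins=256)
        centers = 0.5 * (edges[:-1] + edges[1:])
        direct = fit_em(v, 1)
        binned = fit_em((centers, counts), 1)
        assert binned.means[0] == pytest.approx(direct.means[0], abs=1e-12)


class TestMessageLength:
    def test_penalty_monotone_in_components(self):
        one = make_mixture([1.0], [0.5], [0.01], loglik=-100.0)
        two = make_mixture([0.5, 0.5], [0.3, 0.7], [0.01, 0.01], loglik=-100.0)
        assert message_length(one) < message_length(two)

    def test_bimodal_prefers_two(self, rng):
        v = bimodal_sample(rng)
        assert fit_em(v, 2).message_length < fit_em(v, 1).message_length

    def test_unimodal_prefers_one(self, rng):
        v = rng.normal(0.5, 0.05, 20000)
        assert fit_em(v, 1).message_length < fit_em(v, 2).message_length

    def test_zero_weight_component_excluded(self):
        two = make_mixture([1.0, 0.0], [0.3, 0.7], [0.01, 0.01], loglik=-50.0)
        one = make_mixture([1.0], [0.3], [0.01], loglik=-50.0)
        assert message_length(two) == pytest.approx(message_length(one))


class TestSelectModel:
    def test_bimodal_selects_two(self, rng):
        assert select_model(bimodal_sample(rng)).C == 2

    def test_unimodal_selects_one(self, rng):
        assert select_model(rng.normal(0.5, 0.05, 20000)).C == 1

    def test_degenerate_selects_one(self):
        assert select_model(np.full(500, 0.3)).C == 1


class TestBayesThreshold:
    def test_symmetric_case_is_midpoint(self):
        mix = make_mixture([0.5, 0.5], [0.3, 0.7], [0.002, 0.002])
        t = bayes_threshold(mix)
        assert t.threshold == pytest.approx(0.5, abs=1e-12)
        assert t.method == "bayes" and t.C_selected == 2

    def test_weighted_densities_equal_at_threshold(self, rng):
        for _ in range(20):
            mix = _random_mixture(rng)
            t = bayes_threshold(mix).threshold
            d1, d2 = _weighted_density(mix, t)
            assert d1 == pytest.approx(d2, abs=1e-9)

    def test_matches_grid_search(self, rng):
        for _ in range(30):
            mix = _random_mixture(rng)
            t = bayes_threshold(mix).threshold
            assert t == pytest.approx(grid_crossover(mix), abs=1e-5)

    def test_threshold_between_means(self, rng):
        for _ in range(20):
            mix = _random_mixture(rng)
            t = bayes_threshold(mix).threshold
            assert mix.means[0] <= t <= mix.means[1]

    def test_identical_means_rejected(self):
        mix = make_mixture([0.5, 0.5], [0.5, 0.5], [0.01, 0.01])
        with pytest.raises(ValueError, match="not separated"):
            bayes_threshold(mix)

    def test_requires_two_components(self):
        with pytest.raises(ValueError, match="2-component"):
            bayes_threshold(make_mixture([1.0], [0.5], [0.01]))


class TestKurtosisThreshold:
    def test_symmetric_sample_no_rejection(self):
        v = np.concatenate([np.linspace(0.3, 0.7, 1001)] * 3)
        model = fit_em(v, 1)
        t = kurtosis_threshold(v, model)
        assert t.threshold == np.inf
        assert t.method == "kurtosis" and t.C_selected == 1

    def test_upper_tail_contamination_rejected(self, rng):
        v = np.concatenate([
            rng.normal(0.5, 0.05, 19600), rng.normal(0.95, 0.005, 400)
        ])
        model = fit_em(v, 1)
        t = kurtosis_threshold(v, model)
        assert t.foreground_side == "below"
        assert 0.5 < t.threshold < 0.95
        contaminant = v[v > 0.9]
        assert (contaminant > t.threshold).mean() >= 0.90

    def test_mirrored_contamination_symmetric(self, rng):
        upper = np.concatenate([
            rng.normal(0.5, 0.05, 19600), rng.normal(0.95, 0.005, 400)
        ])
        lower = 1 - upper  # exact mirror: contamination at 0.05
        t_up = kurtosis_threshold(upper, fit_em(upper, 1))
        t_lo = kurtosis_threshold(lower, fit_em(lower, 1))
        assert t_up.foreground_side == "below"
        assert t_lo.foreground_side == "above"
        assert t_lo.threshold == pytest.approx(1 - t_up.threshold, abs=1e-6)


def _random_mixture(rng):
    """Random 2-component mixture with a unique crossover between the means
    (the weighted densities change order over [mu1, mu2]); with extreme
    weight/variance imbalance the equality can have two interior roots and
    no single threshold reproduces the MAP rule."""
    while True:
        p = rng.uniform(0.1, 0.9)
        mix = make_mixture(
            weights=[p, 1 - p],
            means=[rng.uniform(0.0, 0.4), rng.uniform(0.6, 1.0)],
            variances=rng.uniform(0.01, 0.1, 2) ** 2,
        )
        lo = _weighted_density(mix, mix.means[0])
        hi = _weighted_density(mix, mix.means[1])
        if lo[0] > lo[1] and hi[1] > hi[0]:
            return mix


def _weighted_density(mix, x):
    out = []
    for w, mu, var in zip(mix.weights, mix.means, mix.variances):
        out.append(w * np.exp(-0.5 * (x - mu) ** 2 / var) / np.sqrt(2 * np.pi * var))
    return out
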