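"""Calibration engine: likelihood, sampler, diagnostics, posterior operations."""

import numpy as np
import pytest
from scipy import stats

from pinehydro import bayes


class LinearModel(bayes.ResponseModel):
    name = "linear"
    param_names = ["a", "b"]

    def predict(self, theta, x):
        theta = np.asarray(theta, dtype=float)
        if theta.ndim > 1:
            return theta[..., 0, None] + theta[..., 1, None] * x
        return theta[0] + theta[1] * x


class ConstantModel(bayes.ResponseModel):
    name = "constant"
    param_names = ["mu"]

    def predict(self, theta, x):
        theta = np.asarray(theta, dtype=float)
        if theta.ndim > 1:
            return np.broadcast_to(theta[..., 0, None], theta.shape[:-1] + x.shape).copy()
        return np.full_like(x, theta[0])


@pytest.fixture
def lin_priors():
    return bayes.PriorSpec.from_pairs([("a", -10, 10), ("b", -10, 10), ("sigma", 1e-3, 5)])


class TestLogPosterior:
    def test_outside_prior_is_minus_inf(self, lin_priors):
        lp = bayes.log_posterior(
            LinearModel(), [11.0, 0.0, 1.0], np.arange(3.0), np.arange(3.0), lin_priors
        )
        assert lp == -np.inf

    def test_single_datum_at_mode(self):
        priors = bayes.PriorSpec.from_pairs([("mu", -5, 5)])
        sigma = 0.7
        lp = bayes.log_posterior(
            ConstantModel(), [1.0], np.array([0.0]), np.array([1.0]), priors, sigma=sigma
        )
        expected = -np.log(sigma * np.sqrt(2 * np.pi)) + priors.log_density
        assert lp == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_density_product(self, rng, lin_priors):
        """Gaussian likelihood equals an explicit per-point density product."""
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        theta = np.array([0.3, -1.2, 0.8])
        lp = bayes.log_posterior(LinearModel(), theta, x, y, lin_priors)
        dens = stats.norm.logpdf(y, loc=theta[0] + theta[1] * x, scale=theta[2]).sum()
        assert lp == pytest.approx(dens + lin_priors.log_density, rel=1e-12)


class TestSampler:
    def test_same_seed_bit_identical(self, lin_priors, rng):
        x = rng.normal(size=20)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.3, 20)
        cfg = bayes.CalibrationConfig(seed=11, iterations=2000, burn_in=500)
        p1 = bayes.calibrate(LinearModel(), x, y, lin_priors, cfg)
        p2 = bayes.calibrate(LinearModel(), x, y, lin_priors, cfg)
        np.testing.assert_array_equal(p1.chains, p2.chains)

    def test_conjugate_gaussian_mean(self, rng):
        """Posterior of a Gaussian mean with known sigma matches closed form."""
        sigma = 2.0
        n = 40
        y = rng.normal(3.0, sigma, n)
        priors = bayes.PriorSpec.from_pairs([("mu", -50, 50)])
        cfg = bayes.CalibrationConfig(seed=5, iterations=12000, burn_in=4000)
        post = bayes.calibrate(
            ConstantModel(), np.zeros(n), y, priors, cfg, sigma=sigma
        )
        flat = post.flat_samples()[:, 0]
        post_sd = sigma / np.sqrt(n)
        # MC error of the mean with autocorrelated chains: generous 5x factor
        assert flat.mean() == pytest.approx(y.mean(), abs=5 * post_sd / np.sqrt(len(flat) / 20))
        assert flat.std() == pytest.approx(post_sd, rel=0.1)
        assert np.all(post.rhat <= 1.05)

    def test_acceptance_rate_reasonable(self, lin_priors, rng):
        x = rng.normal(size=30)
        y = 0.5 - 1.5 * x + rng.normal(0, 0.4, 30)
        cfg = bayes.CalibrationConfig(seed=2, iterations=4000, burn_in=1000)
        post = bayes.calibrate(LinearModel(), x, y, lin_priors, cfg)
        assert 0.05 < post.acceptance_rate < 0.9


class TestGelmanRubin:
    def test_exact_copies_below_one(self, rng):
        c = rng.normal(size=(1, 200, 2))
        chains = np.repeat(c, 3, axis=0)
        n = 200
        np.testing.assert_allclose(
            bayes.gelman_rubin(chains), np.sqrt((n - 1) / n), rtol=1e-12
        )

    def test_same_distribution_near_one(self, rng):
        chains = rng.normal(size=(3, 10_000, 1))
        assert bayes.gelman_rubin(chains)[0] < 1.01

    def test_disjoint_chains_flagged(self, rng):
        chains = np.stack([
            0.0 + 0.01 * rng.normal(size=(500, 1)),
            10.0 + 0.01 * rng.normal(size=(500, 1)),
        ])
        assert bayes.gelman_rubin(chains)[0] > 1.1

    def test_zero_variance_undefined(self):
        chains = np.ones((2, 50, 1))
        assert np.isnan(bayes.gelman_rubin(chains)[0])


class TestPosteriorOps:
    def _point_mass(self, value, n=500, names=("a",)):
        return bayes.PosteriorSet(
            param_names=list(names),
            samples=np.full((n, len(names)), float(value)),
            merged=True,
            unit_converged=True,
        )

    def test_merge_single_identity(self, rng):
        chains = rng.normal(size=(3, 400, 1))
        p = bayes.PosteriorSet(param_names=["a"], chains=chains, rhat=np.array([1.0]))
        merged = bayes.merge_posteriors([p])
        np.testing.assert_allclose(
            np.sort(merged.flat_samples()[:, 0]), np.sort(p.flat_samples()[:, 0])
        )

    def test_merge_point_masses_median(self):
        merged = bayes.merge_posteriors([self._point_mass(2.0), self._point_mass(6.0)])
        assert np.median(merged.flat_samples()[:, 0]) == pytest.approx(4.0)

    def test_merge_covers_union_spread(self, rng):
        a = bayes.PosteriorSet(
            param_names=["a"], samples=rng.normal(0.0, 0.1, (1000, 1)), merged=True,
            unit_converged=True,
        )
        b = bayes.PosteriorSet(
            param_names=["a"], samples=rng.normal(5.0, 0.1, (1000, 1)), merged=True,
            unit_converged=True,
        )
        merged = bayes.merge_posteriors([a, b])
        lo, hi = bayes.credible_interval(merged.flat_samples()[:, 0])
        assert lo < 0.2 and hi > 4.8

    def test_merge_mismatched_params_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            bayes.merge_posteriors(
                [self._point_mass(1.0, names=("a",)), self._point_mass(1.0, names=("b",))]
            )

    def test_credible_interval_uniform(self, rng):
        samples = rng.uniform(0, 1, 100_000)
        lo, hi = bayes.credible_interval(samples, 0.95)
        assert lo == pytest.approx(0.025, abs=0.005)
        assert hi == pytest.approx(0.975, abs=0.005)

    def test_credible_interval_needs_samples(self, rng):
        with pytest.raises(ValueError):
            bayes.credible_interval(rng.normal(size=50))

    @pytest.mark.parametrize(
        "a, b, expected",
        [((1, 2), (3, 4), True), ((1, 3), (2, 4), False), ((3, 4), (1, 2), True)],
    )
    def test_ci_overlap_decision(self, a, b, expected):
        assert bayes.ci_overlap_decision(a, b) is expected


class TestPosteriorPredictive:
    def test_degenerate_posterior_collapses_band(self):
        post = bayes.PosteriorSet(
            param_names=["a", "b", "sigma"],
            samples=np.array([[1.0, 2.0, 0.1]]),
            merged=True,
            unit_converged=True,
        )
        grid = np.linspace(-1, 1, 5)
        med, lo, hi = bayes.posterior_predictive(LinearModel(), post, grid, draws=200)
        np.testing.assert_allclose(med, 1.0 + 2.0 * grid)
        np.testing.assert_allclose(lo, med)
        np.testing.assert_allclose(hi, med)

    def test_vpd_band_at_reference_equals_gc_ref_quantiles(self, rng):
        samples = np.column_stack([
            rng.normal(0.2, 0.02, 4000), rng.normal(0.1, 0.01, 4000),
            np.full(4000, 0.01),
        ])
        post = bayes.PosteriorSet(
            param_names=["gc_ref", "m", "sigma"], samples=samples, merged=True,
            unit_converged=True,
        )
        model = bayes.VpdModel(reference_vpd=1.0)
        med, lo, hi = bayes.posterior_predictive(
            model, post, np.array([1.0]), draws=5000, rng=np.random.default_rng(0)
        )
        assert med[0] == pytest.approx(np.median(samples[:, 0]), abs=2e-3)

    def test_band_shrinks_with_posterior_sd(self, rng):
        grid = np.linspace(0.5, 2.5, 7)
        widths = []
        for sd in (0.05, 0.005):
            samples = np.column_stack([
                rng.normal(0.2, sd, 2000), rng.normal(0.1, sd / 2, 2000),
                np.full(2000, 0.01),
            ])
            post = bayes.PosteriorSet(
                param_names=["gc_ref", "m", "sigma"], samples=samples, merged=True,
                unit_converged=True,
            )
            _, lo, hi = bayes.posterior_predictive(
                bayes.VpdModel(), post, grid, draws=2000,
                rng=np.random.default_rng(1),
            )
            widths.append(np.mean(hi - lo))
        assert widths[1] < widths[0] / 5


class TestResponseModels:
    def test_vpd_model_reference_point(self):
        model = bayes.VpdModel(reference_vpd=1.0)
        assert model.predict(np.array([0.2, 0.1]), np.array([1.0]))[0] == pytest.approx(0.2)

    def test_closure_model_psi_close(self):
        model = bayes.ClosureModel()
        theta = np.array([-1.119, 3.0])
        psi_close = model.psi_close(theta)
        gc_at_close = model.predict(theta, np.array([psi_close]))[0]
        assert gc_at_close == pytest.approx(0.05, rel=1e-10)
        assert psi_close == pytest.approx(-2.1, abs=0.01)

    def test_closure_model_bounded(self):
        model = bayes.ClosureModel()
        out = model.predict(np.array([-1.5, 4.0]), np.linspace(-6, 0, 50))
        assert np.all((out > 0) & (out < 1))

    def test_closure_psi_close_invariant_to_gc_scaling(self, rng):
        """Ψ at closure depends only on relative gc, not its absolute scale."""
        model = bayes.ClosureModel()
        psi = np.linspace(-3.0, -0.3, 30)
        truth = np.array([-1.3, 3.5])
        gc_rel = model.predict(truth, psi) + rng.normal(0, 0.02, psi.size)
        cfg = bayes.CalibrationConfig(seed=9, iterations=8000, burn_in=3000)
        post = bayes.calibrate(
            model, psi, gc_rel, bayes.default_closure_priors(), cfg
        )
        # affine-rescaled input, renormalized to relative units, gives same answer
        post2 = bayes.calibrate(
            model, psi, (gc_rel * 0.37) / 0.37, bayes.default_closure_priors(), cfg
        )
        c1 = model.psi_close(post.flat_samples()[:, :2])
        c2 = model.psi_close(post2.flat_samples()[:, :2])
        assert np.median(c1) == pytest.approx(np.median(c2), rel=1e-12)
        assert np.median(c1) == pytest.approx(
            model.psi_close(truth), abs=0.1
        )
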