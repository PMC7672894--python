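import numpy as np
import pytest
import scipy.integrate
import scipy.stats

from vafmix import (
    BetaComponent,
    BetaParetoMixture,
    ParetoComponent,
    beta_density,
    fit_beta_moment_match,
    fit_mixture,
    fit_pareto_shape,
    mixture_nll,
    pareto_density,
    random_model,
    responsibilities,
    sample_from,
)
from vafmix.errors import (
    DegenerateClusterError,
    DegenerateTailError,
    ValidationError,
)
from vafmix.io import FrequencyDataset

from conftest import beta_ab, make_model


class TestDensities:
    def test_pareto_closed_forms(self):
        c = ParetoComponent(scale=0.05, shape=1.0)
        assert pareto_density(0.05, c)[0] == pytest.approx(1.0 / 0.05)
        assert pareto_density(0.1, c)[0] == pytest.approx(5.0)
        assert pareto_density(0.01, c)[0] == 0.0

    def test_pareto_integrates_to_one(self):
        c = ParetoComponent(scale=0.05, shape=1.7)
        val, _ = scipy.integrate.quad(lambda x: pareto_density(x, c)[0], 0.05, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_beta_closed_forms(self):
        assert beta_density(0.5, BetaComponent(1, 1))[0] == pytest.approx(1.0)
        assert beta_density(0.5, BetaComponent(2, 2))[0] == pytest.approx(1.5)

    def test_beta_integrates_to_one(self):
        c = BetaComponent(7.3, 2.1)
        val, _ = scipy.integrate.quad(lambda x: beta_density(x, c)[0], 0, 1)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_beta_outside_open_interval_rejected(self):
        with pytest.raises(ValidationError):
            beta_density(0.0, BetaComponent(2, 2))


class TestNLL:
    def test_uniform_single_point_is_zero(self):
        m = make_model(betas=[(1.0, 1.0)], weights=[1.0])
        assert mixture_nll(np.array([0.5]), m) == pytest.approx(0.0)

    def test_tail_only_closed_form(self):
        m = make_model(betas=[], weights=[1.0], tail=(0.05, 1.0))
        m.n_beta = 0
        nll = mixture_nll(np.array([0.05, 0.1]), m)
        assert nll == pytest.approx(-np.log(20.0) - np.log(5.0))

    def test_matches_scipy_bruteforce(self, recovery_model):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.051, 0.95, 50)
        m = recovery_model
        # independent oracle: scipy.stats densities, direct per-point sum
        dens = (
            m.weights_[0] * scipy.stats.pareto.pdf(x, b=1.5, scale=0.05)
            + m.weights_[1] * scipy.stats.beta.pdf(x, *beta_ab(0.5, 0.002))
            + m.weights_[2] * scipy.stats.beta.pdf(x, *beta_ab(0.25, 0.002))
        )
        assert mixture_nll(x, m) == pytest.approx(-np.log(dens).sum(), abs=1e-8)


class TestResponsibilities:
    def test_identical_components_split_evenly(self):
        m = make_model(betas=[(3.0, 3.0), (3.0, 3.0)], weights=[0.5, 0.5])
        z = responsibilities(np.array([0.2, 0.7]), m)
        np.testing.assert_allclose(z, 0.5)

    def test_below_scale_has_zero_tail_mass(self, recovery_model):
        z = responsibilities(np.array([0.03]), recovery_model)
        assert z[0, 0] == 0.0
        assert z.sum() == pytest.approx(1.0)

    def test_matches_bayes_rule_oracle(self, recovery_model):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.06, 0.9, 20)
        m = recovery_model
        num = np.column_stack(
            [
                m.weights_[0] * scipy.stats.pareto.pdf(x, b=1.5, scale=0.05),
                m.weights_[1] * scipy.stats.beta.pdf(x, *beta_ab(0.5, 0.002)),
                m.weights_[2] * scipy.stats.beta.pdf(x, *beta_ab(0.25, 0.002)),
            ]
        )
        np.testing.assert_allclose(
            responsibilities(x, m), num / num.sum(1, keepdims=True), atol=1e-10
        )


class TestComponentEstimators:
    def test_moment_match_closed_form(self):
        # m=0.5, v=0.05 -> common factor 4 -> Beta(2, 2)
        x = np.array([0.5 - np.sqrt(0.05), 0.5 + np.sqrt(0.05)])
        c = fit_beta_moment_match(x, np.ones(2))
        assert (c.a, c.b) == (pytest.approx(2.0), pytest.approx(2.0))

    def test_symmetric_data_gives_symmetric_shapes(self):
        x = np.array([0.3, 0.4, 0.6, 0.7])
        c = fit_beta_moment_match(x, np.ones(4))
        assert c.a == pytest.approx(c.b, abs=1e-9)

    def test_moment_match_recovers_beta_mean(self):
        x = np.random.default_rng(3).beta(10, 30, 10_000)
        c = fit_beta_moment_match(x, np.ones_like(x))
        assert c.mean == pytest.approx(0.25, abs=0.01)

    def test_zero_variance_cluster_degenerates(self):
        with pytest.raises(DegenerateClusterError):
            fit_beta_moment_match(np.array([0.4, 0.4, 0.4]), np.ones(3))

    def test_zero_weight_cluster_degenerates(self):
        with pytest.raises(DegenerateClusterError):
            fit_beta_moment_match(np.array([0.2, 0.4]), np.zeros(2))

    def test_hill_single_point(self):
        assert fit_pareto_shape(np.array([0.05 * np.e]), np.ones(1), 0.05) == \
            pytest.approx(1.0)

    def test_hill_two_points(self):
        x = np.array([0.05, 0.05 * np.e])
        assert fit_pareto_shape(x, np.ones(2), 0.05) == pytest.approx(2.0)

    def test_hill_recovers_shape(self):
        x = scipy.stats.pareto.rvs(b=1.5, scale=0.05, size=10_000,
                                   random_state=11)
        assert fit_pareto_shape(x, np.ones_like(x), 0.05) == pytest.approx(
            1.5, abs=0.05
        )

    def test_all_mass_at_scale_degenerates(self):
        with pytest.raises(DegenerateTailError):
            fit_pareto_shape(np.full(5, 0.05), np.ones(5), 0.05)


class TestFit:
    def test_single_beta_recovery(self):
        x = np.random.default_rng(5).beta(20, 20, 2000)
        m = fit_mixture(x, k=1, tail=False, seed=1, restarts=3)
        assert m.betas_[0].mean == pytest.approx(0.5, abs=0.02)
        assert m.converged_

    def test_three_component_recovery(self, recovery_model):
        ds, _ = sample_from(recovery_model, 5000, seed=9)
        m = fit_mixture(ds, k=2, tail=True, seed=2, restarts=6)
        np.testing.assert_allclose(m.weights_, [0.3, 0.4, 0.3], atol=0.05)
        assert m.betas_[0].mean == pytest.approx(0.5, abs=0.02)
        assert m.betas_[1].mean == pytest.approx(0.25, abs=0.02)
        # the ML tail shape carries the documented upward truncation bias
        # of fitting an untruncated Pareto to frequencies confined below 1
        assert 1.4 < m.tail_.shape < 1.9

    def test_mle_mode_monotone_nll(self, recovery_model):
        ds, _ = sample_from(recovery_model, 1500, seed=10)
        m = fit_mixture(ds, k=2, tail=True, seed=3, restarts=2,
                        beta_estimator="mle")
        diffs = np.diff(m.fit_trace_)
        assert (diffs <= 1e-7 * np.abs(m.fit_trace_[:-1])).all()

    def test_moment_match_close_to_mle_likelihood(self, recovery_model):
        ds, _ = sample_from(recovery_model, 2000, seed=12)
        mm = fit_mixture(ds, k=2, tail=True, seed=4, restarts=4)
        ml = fit_mixture(ds, k=2, tail=True, seed=4, restarts=4,
                         beta_estimator="mle")
        assert abs(mm.nll_ - ml.nll_) / ds.n < 0.01  # nats per point

    def test_canonical_order_and_init_invariance(self, recovery_model):
        ds, _ = sample_from(recovery_model, 3000, seed=13)
        a = fit_mixture(ds, k=2, tail=True, seed=100, restarts=5)
        b = fit_mixture(ds, k=2, tail=True, seed=2177, restarts=5)
        means_a = [c.mean for c in a.betas_]
        assert means_a == sorted(means_a, reverse=True)
        np.testing.assert_allclose(means_a, [c.mean for c in b.betas_], atol=1e-3)
        np.testing.assert_allclose(a.weights_, b.weights_, atol=1e-3)

    def test_lambda_counts_free_parameters(self, recovery_model):
        ds, _ = sample_from(recovery_model, 500, seed=14)
        m = fit_mixture(ds, k=2, tail=True, seed=5, restarts=2)
        assert m.lambda_ == 2 * 2 + 1 + (3 - 1)
        m2 = fit_mixture(ds, k=1, tail=False, seed=5, restarts=2)
        assert m2.lambda_ == 2

    def test_simplex_invariants(self, recovery_model):
        ds, _ = sample_from(recovery_model, 800, seed=15)
        m = fit_mixture(ds, k=2, tail=True, seed=6, restarts=3)
        assert m.weights_.sum() == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(m.responsibilities_.sum(1), 1.0, atol=1e-8)

    def test_boundary_frequencies_rejected(self):
        with pytest.raises(ValidationError):
            fit_mixture(np.array([0.0, 0.5, 0.7]), k=1, tail=False, restarts=1)

    def test_needs_enough_points(self):
        with pytest.raises(ValidationError):
            fit_mixture(np.array([0.5]), k=2, tail=False, restarts=1)


class TestGenerativeUtilities:
    def test_single_component_labels(self):
        m = make_model(betas=[(5.0, 5.0)], weights=[1.0])
        _, labels = sample_from(m, 50, seed=1)
        assert (labels == 0).all()

    def test_label_proportions_follow_weights(self):
        m = make_model(betas=[(8.0, 8.0), (8.0, 24.0)], weights=[0.3, 0.7])
        _, labels = sample_from(m, 100_000, seed=2)
        assert (labels == 0).mean() == pytest.approx(0.3, abs=0.01)

    def test_tail_draw_mean_matches_analytic_moment(self):
        m = make_model(betas=[(50.0, 10.0)], weights=[0.8, 0.2],
                       tail=(0.05, 2.5))
        x, labels = m.sample(60_000, random_state=3)
        draws = x[labels == 0]
        # analytic first moment of the Pareto restricted to (scale, 1)
        c = m.tail_
        mass = 1.0 - c.scale**c.shape
        num, _ = scipy.integrate.quad(
            lambda v: v * pareto_density(v, c)[0], c.scale, 1.0
        )
        expected = num / mass
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se
        # the untruncated closed-form mean is the limit the draws approach
        assert expected == pytest.approx(c.mean, rel=0.02)

    def test_random_model_is_valid_and_seeded(self):
        a = random_model(3, tail=True, seed=4)
        b = random_model(3, tail=True, seed=4)
        assert a.weights_.sum() == pytest.approx(1.0)
        assert [c.mean for c in a.betas_] == [c.mean for c in b.betas_]
        means = [c.mean for c in a.betas_]
        assert means == sorted(means, reverse=True)
        assert all(0 < c.variance < c.mean * (1 - c.mean) for c in a.betas_)

    def test_samples_stay_inside_open_interval(self):
        m = make_model(betas=[(2.0, 2.0)], weights=[0.5, 0.5], tail=(0.05, 0.8))
        ds, _ = sample_from(m, 5000, seed=5)
        x = ds.frequencies
        assert ((x > 0) & (x < 1)).all()

    def test_serialisation_roundtrip(self, recovery_model):
        ds, _ = sample_from(recovery_model, 600, seed=16)
        m = fit_mixture(ds, k=2, tail=True, seed=7, restarts=2)
        back = BetaParetoMixture.from_dict(m.to_dict())
        assert back.nll(ds.frequencies) == pytest.approx(m.nll_, rel=1e-12)
        np.testing.assert_allclose(back.weights_, m.weights_)
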