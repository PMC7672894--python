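import numpy as np
import pytest

from vafmix import (
    FitConfig,
    assign_new,
    entropy,
    filter_clusters,
    fit_mixture,
    reduced_entropy,
    sample_from,
    score_model,
    select_model,
)
from vafmix.errors import ConfigurationError, FitError, ValidationError
from vafmix.simulate import SimulationConfig, simulate_tumour

from conftest import beta_ab, make_model


class TestEntropy:
    def test_hard_assignments_have_zero_entropy(self):
        z = np.eye(3)[[0, 1, 2, 0]]
        assert entropy(z) == 0.0

    def test_uniform_binary_rows(self):
        n = 17
        z = np.full((n, 2), 0.5)
        assert entropy(z) == pytest.approx(n * np.log(2))

    def test_matches_elementwise_bruteforce(self):
        rng = np.random.default_rng(0)
        z = rng.dirichlet(np.ones(4), 20)
        brute = -sum(
            v * np.log(v) for row in z for v in row if v > 0
        )
        assert entropy(z) == pytest.approx(brute, abs=1e-12)


class TestReducedEntropy:
    def test_one_hot_beta_rows_equal_plain_entropy(self):
        z = np.zeros((5, 3))
        z[:, 1] = 1.0
        assert reduced_entropy(z) == 0.0 == entropy(z)

    def test_tail_dominated_rows_are_dropped(self):
        z = np.array([[0.6, 0.2, 0.2]])
        assert reduced_entropy(z) == 0.0

    def test_matches_strip_renormalise_oracle(self):
        rng = np.random.default_rng(1)
        z = rng.dirichlet(np.ones(4), 30)
        keep = z.argmax(1) != 0
        zb = z[keep][:, 1:]
        zb = zb / zb.sum(1, keepdims=True)
        assert reduced_entropy(z) == pytest.approx(entropy(zb), abs=1e-12)

    def test_without_tail_returns_plain_entropy(self):
        rng = np.random.default_rng(2)
        z = rng.dirichlet(np.ones(3), 10)
        assert reduced_entropy(z, has_tail=False) == entropy(z)


@pytest.fixture(scope="module")
def fitted(recovery_model):
    ds, _ = sample_from(recovery_model, 2000, seed=20)
    model = fit_mixture(ds, k=2, tail=True, seed=8, restarts=4)
    return ds, model


class TestScores:
    def test_score_identities_hold_exactly(self, fitted):
        ds, model = fitted
        s = score_model(ds, model)
        assert s.bic == pytest.approx(2 * s.nll + model.lambda_ * np.log(ds.n),
                                      rel=1e-12)
        assert s.icl == pytest.approx(s.bic + s.entropy_full, rel=1e-12)
        assert s.reicl == pytest.approx(s.bic + s.entropy_reduced, rel=1e-12)

    def test_score_ordering(self, fitted):
        ds, model = fitted
        s = score_model(ds, model)
        assert s.icl >= s.reicl >= s.bic
        assert s.entropy_reduced <= s.entropy_full

    def test_overlapping_betas_raise_reduced_entropy(self):
        x = np.concatenate(
            [
                np.random.default_rng(3).beta(*beta_ab(0.45, 0.002), 300),
                np.random.default_rng(4).beta(*beta_ab(0.55, 0.002), 300),
            ]
        )
        overlapping = make_model(
            betas=[beta_ab(0.52, 0.003), beta_ab(0.48, 0.003)],
            weights=[0.1, 0.45, 0.45],
            tail=(0.05, 1.5),
        )
        separated = make_model(
            betas=[beta_ab(0.55, 0.002), beta_ab(0.45, 0.002)],
            weights=[0.1, 0.45, 0.45],
            tail=(0.05, 1.5),
        )
        so = score_model(x, overlapping)
        ss = score_model(x, separated)
        assert so.entropy_reduced > ss.entropy_reduced


class TestSelectModel:
    def test_two_separated_betas_with_tail_selected(self, recovery_model):
        ds, _ = sample_from(recovery_model, 5000, seed=21)
        rep = select_model(ds, FitConfig(seed=1, restarts=5))
        assert rep.best.k == 2 and rep.best.tail
        assert rep.best.architecture == "polyclonal"

    def test_tail_free_data_drops_tail(self):
        m = make_model(
            betas=[beta_ab(0.6, 0.002), beta_ab(0.3, 0.002)],
            weights=[0.5, 0.5],
        )
        ds, _ = sample_from(m, 4000, seed=22)
        rep = select_model(ds, FitConfig(seed=2, restarts=5))
        assert not rep.best.tail
        assert rep.best.k == 2

    def test_monoclonal_simulation_selects_k1_tail(self):
        sim = simulate_tumour(SimulationConfig(seed=77, driver_time=None))
        rep = select_model(sim.observed, FitConfig(seed=3, restarts=6))
        assert rep.best.k == 1 and rep.best.tail
        assert rep.best.architecture == "monoclonal"

    def test_parallel_matches_serial(self, recovery_model):
        ds, _ = sample_from(recovery_model, 1200, seed=23)
        a = select_model(ds, FitConfig(seed=4, restarts=3, parallel=1))
        b = select_model(ds, FitConfig(seed=4, restarts=3, parallel=2))
        assert a.best.signature == b.best.signature
        assert a.best.scores.reicl == pytest.approx(b.best.scores.reicl,
                                                    rel=1e-12)

    def test_selection_consistency_improves_with_n(self, recovery_model):
        hits = {}
        for n in (1500, 6000):
            ok = 0
            for s in range(5):
                ds, _ = sample_from(recovery_model, n, seed=100 + s)
                rep = select_model(ds, FitConfig(seed=s, restarts=4))
                ok += rep.best.k == 2 and rep.best.tail
            hits[n] = ok
        assert hits[6000] >= hits[1500]

    def test_ranked_report_and_serialisation(self, recovery_model):
        ds, _ = sample_from(recovery_model, 1000, seed=24)
        rep = select_model(ds, FitConfig(seed=5, restarts=3))
        ranked = rep.ranked()
        scores = [getattr(c.scores, "reicl") for c in ranked]
        assert scores == sorted(scores)
        d = rep.to_dict()
        assert d["best"]["signature"] == rep.best.signature
        assert rep.best.signature in rep.summary()


class TestFilterClusters:
    def test_small_pi_cluster_removed_and_renormalised(self):
        m = make_model(
            betas=[beta_ab(0.5, 0.002), beta_ab(0.25, 0.002)],
            weights=[0.5, 0.49, 0.01],
            tail=(0.05, 1.5),
        )
        rng = np.random.default_rng(6)
        x = np.concatenate([
            0.05 / (1 - rng.uniform(0, 0.9, 200)),
            rng.beta(*beta_ab(0.5, 0.002), 200),
        ])
        x = np.clip(x, 0.051, 0.99)
        out = filter_clusters(m, x, min_pi=0.02, min_count=0)
        assert len(out.betas_) == 1
        assert out.weights_.sum() == pytest.approx(1.0)
        assert out.tail_ is not None  # the tail is never filtered

    def test_zero_thresholds_identity(self, recovery_model):
        ds, _ = sample_from(recovery_model, 800, seed=25)
        model = fit_mixture(ds, k=2, tail=True, seed=9, restarts=3)
        assert filter_clusters(model, ds, 0.0, 0) is model

    def test_low_count_cluster_removed_with_reassignment_oracle(self):
        m = make_model(
            betas=[beta_ab(0.7, 0.002), beta_ab(0.45, 0.002),
                   beta_ab(0.2, 0.001)],
            weights=[0.4, 0.4, 0.2],
        )
        rng = np.random.default_rng(7)
        x = np.concatenate([
            rng.beta(*beta_ab(0.7, 0.002), 120),
            rng.beta(*beta_ab(0.45, 0.002), 120),
            rng.beta(*beta_ab(0.2, 0.001), 5),
        ])
        out = filter_clusters(m, x, min_pi=0.0, min_count=10)
        assert len(out.betas_) == 2
        # surviving assignments match a brute-force recomputation
        z = out.predict_proba(x)
        import scipy.stats

        num = np.column_stack([
            out.weights_[j] * scipy.stats.beta.pdf(x, c.a, c.b)
            for j, c in enumerate(out.betas_)
        ])
        np.testing.assert_allclose(z, num / num.sum(1, keepdims=True),
                                   atol=1e-10)

    def test_removing_everything_fails(self, recovery_model):
        ds, _ = sample_from(recovery_model, 500, seed=26)
        model = fit_mixture(ds, k=1, tail=True, seed=10, restarts=2)
        with pytest.raises(FitError):
            filter_clusters(model, ds, min_pi=0.99, min_count=10**6)


class TestAssignNew:
    def test_training_point_identical_row(self, recovery_model):
        ds, _ = sample_from(recovery_model, 600, seed=27)
        model = fit_mixture(ds, k=2, tail=True, seed=11, restarts=2)
        z_train = model.predict_proba(ds.frequencies[:5])
        z_new, labels = assign_new(model, ds.frequencies[:5])
        np.testing.assert_array_equal(z_train, z_new)

    def test_below_scale_zero_tail(self, recovery_model):
        z, _ = assign_new(recovery_model, [0.03])
        assert z[0, 0] == 0.0

    def test_fifty_new_points_match_oracle(self, recovery_model):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.06, 0.9, 50)
        z, labels = assign_new(recovery_model, x)
        np.testing.assert_allclose(
            z, recovery_model.predict_proba(x), atol=1e-12
        )
        np.testing.assert_array_equal(labels, z.argmax(1))

    def test_boundary_rejected(self, recovery_model):
        with pytest.raises(ValidationError):
            assign_new(recovery_model, [0.0, 0.5])


class TestConfigValidation:
    def test_bad_score_rejected(self):
        with pytest.raises(ConfigurationError):
            FitConfig(score="aic")

    def test_empty_k_range_rejected(self):
        with pytest.raises(ConfigurationError):
            FitConfig(k_range=())
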