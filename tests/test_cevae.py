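"""Inference network, decoders, ELBO, training loop and ATE mechanics."""

import numpy as np
import pytest

from cebp import RunConfig
from cebp.cevae import (
    CausalDataset,
    CEVAE,
    elbo,
    estimate_ate,
    gaussian_kl,
    infer_posterior,
    init_model,
    predict_counterfactuals,
    run_replicates,
    train,
)
from cebp._autodiff import Tensor
from cebp.cevae import _np_mlp, _np_posterior, decode


@pytest.fixture
def toy_params(tiny_cfg):
    return init_model((6, 3), tiny_cfg, seed=0)


@pytest.fixture
def toy_batch():
    rng = np.random.default_rng(0)
    x = (rng.random((12, 6)) < 0.3).astype(float)
    m = np.array([0, 1] * 6, dtype=float)
    y = rng.normal(size=12)
    return x, m, y


class TestCausalDataset:
    def test_validation(self):
        with pytest.raises(ValueError, match="binary"):
            CausalDataset(np.array([[2.0]]), np.array([1]), np.array([1.0]))
        with pytest.raises(ValueError, match="arms"):
            CausalDataset(
                np.zeros((3, 2)), np.array([1, 1, 1]), np.array([1.0, 2.0, 3.0])
            )

    def test_subset_keeps_alignment(self, tiny_sim):
        ds = tiny_sim.dataset
        sub = ds.subset(np.arange(60))
        assert sub.n_samples == 60
        np.testing.assert_array_equal(sub.Y, ds.Y[:60])


class TestInitModel:
    def test_seeded_determinism(self, tiny_cfg):
        a = init_model((6, 3), tiny_cfg, seed=9)
        b = init_model((6, 3), tiny_cfg, seed=9)
        for p, q in zip(a.parameters, b.parameters):
            np.testing.assert_array_equal(p.data, q.data)

    def test_latent_head_dimensions(self):
        cfg = RunConfig(latent_dim=20, hidden_width=16, hidden_depth=3)
        params = init_model((200, 20), cfg, seed=0)
        # arm heads emit 20 means + 20 sds
        assert params.f0_net.weights[-1].data.shape[1] == 40
        assert params.f1_net.weights[-1].data.shape[1] == 40
        assert params.px_net.weights[-1].data.shape[1] == 200

    def test_depth_configuration(self):
        cfg = RunConfig(latent_dim=4, hidden_width=8, hidden_depth=3)
        params = init_model((10, 4), cfg, seed=0)
        # deep decoders carry hidden_depth hidden layers (+ output layer)
        assert len(params.px_net.weights) == 4
        assert len(params.py0_net.weights) == 4
        # treatment networks stay single-hidden-layer
        assert len(params.pm_net.weights) == 2
        assert len(params.qm_net.weights) == 2

    def test_invalid_dims_error(self, tiny_cfg):
        with pytest.raises(ValueError):
            init_model((0, 3), tiny_cfg)
        with pytest.raises(ValueError):
            init_model((5, 0), tiny_cfg)


class TestInferPosterior:
    def test_identical_samples_same_posterior(self, toy_params):
        x = np.tile([1.0, 0, 0, 1, 0, 1], (2, 1))
        mu, sd = infer_posterior(x, np.array([0.5, 0.5]), np.array([1.0, 1.0]), toy_params)
        np.testing.assert_allclose(mu.data[0], mu.data[1])
        np.testing.assert_allclose(sd.data[0], sd.data[1])

    def test_arm_specific_heads_are_distinct(self, toy_params):
        x = np.ones((1, 6))
        y = np.array([0.2])
        mu0, _ = infer_posterior(x, y, np.array([0.0]), toy_params)
        mu1, _ = infer_posterior(x, y, np.array([1.0]), toy_params)
        # untrained arm heads differ, so routing must change the output
        assert not np.allclose(mu0.data, mu1.data)

    def test_posterior_sds_strictly_positive(self, toy_params):
        rng = np.random.default_rng(5)
        x = (rng.random((20, 6)) < 0.5).astype(float)
        _, sd = infer_posterior(x, rng.normal(size=20), (rng.random(20) < 0.5).astype(float), toy_params)
        assert np.all(sd.data > 0)


class TestDecode:
    def test_untreated_gating_identity(self, toy_params):
        z = np.random.default_rng(1).normal(size=(4, 3))
        _, _, y_mean = decode(z, np.zeros(4), toy_params)
        np.testing.assert_allclose(
            y_mean.data, _np_mlp(toy_params.py0_net, z), atol=1e-12
        )

    def test_m_probability_in_unit_interval(self, toy_params):
        z = np.random.default_rng(2).normal(size=(50, 3)) * 5
        _, m_prob, _ = decode(z, np.ones(50), toy_params)
        assert np.all(m_prob.data > 0) and np.all(m_prob.data < 1)

    def test_tied_arms_make_y_mean_treatment_free(self, toy_params):
        toy_params.tie_outcome_arms()
        z = np.random.default_rng(3).normal(size=(6, 3))
        _, _, y_treated = decode(z, np.ones(6), toy_params)
        _, _, y_control = decode(z, np.zeros(6), toy_params)
        np.testing.assert_allclose(y_treated.data, y_control.data)


class TestElbo:
    def test_standard_normal_posterior_gives_zero_kl(self):
        mu = Tensor(np.zeros((5, 3)))
        sd = Tensor(np.ones((5, 3)))
        np.testing.assert_allclose(gaussian_kl(mu, sd).data, 0.0, atol=1e-12)

    def test_kl_mean_shift_closed_form(self):
        rng = np.random.default_rng(0)
        mus = rng.normal(size=(8, 4))
        kl = gaussian_kl(Tensor(mus), Tensor(np.ones((8, 4))))
        np.testing.assert_allclose(kl.data, (mus**2).sum(axis=1) / 2, atol=1e-12)

    def test_kl_nonnegative_on_random_posteriors(self):
        rng = np.random.default_rng(1)
        kl = gaussian_kl(
            Tensor(rng.normal(size=(200, 6))),
            Tensor(rng.uniform(0.05, 3.0, size=(200, 6))),
        )
        assert np.all(kl.data >= 0)

    def test_loss_matches_naive_monte_carlo(self, toy_params, toy_batch):
        """Closed-form-KL ELBO equals a plain MC estimate of the same
        expectation (which uses log p(z) - log q(z) draws instead)."""
        x, m, y = toy_batch
        loss, breakdown = elbo((x, m, y), toy_params, n_mc=1000, seed=123)

        mu, sd = _np_posterior(toy_params, x, y, m)
        rng = np.random.default_rng(321)
        draws = 10_000
        per_draw = np.empty((draws, len(m)))
        eps = toy_params.outcome_sd
        for k in range(draws):
            z = mu + sd * rng.standard_normal(mu.shape)
            x_logits = _np_mlp(toy_params.px_net, z)
            m_logit = _np_mlp(toy_params.pm_net, z).ravel()
            y0 = _np_mlp(toy_params.py0_net, z).ravel()
            y1 = _np_mlp(toy_params.py1_net, z).ravel()
            y_mean = m * y1 + (1 - m) * y0
            lx = (x * x_logits - np.logaddexp(0, x_logits)).sum(axis=1)
            lm = m * m_logit - np.logaddexp(0, m_logit)
            ly = -0.5 * ((y - y_mean) / eps) ** 2 - 0.5 * np.log(2 * np.pi) - np.log(eps)
            log_p_z = -0.5 * (z**2).sum(axis=1) - 0.5 * z.shape[1] * np.log(2 * np.pi)
            log_q_z = (
                -0.5 * (((z - mu) / sd) ** 2).sum(axis=1)
                - 0.5 * z.shape[1] * np.log(2 * np.pi)
                - np.log(sd).sum(axis=1)
            )
            per_draw[k] = lx + lm + ly + log_p_z - log_q_z
        mc_expectation = per_draw.mean()
        aux = breakdown["aux_m"] + breakdown["aux_y"]
        mc_loss = -(mc_expectation + aux)
        per_draw_means = per_draw.mean(axis=1)
        se = per_draw_means.std(ddof=1) * np.sqrt(1 / draws + 1 / 1000)
        assert float(loss.data) == pytest.approx(mc_loss, abs=3 * se)

    def test_breakdown_terms_sum_to_loss(self, toy_params, toy_batch):
        loss, b = elbo(toy_batch, toy_params, n_mc=3, seed=0)
        total = -(
            b["rec_x"] + b["rec_m"] + b["rec_y"] - b["kl"] + b["aux_m"] + b["aux_y"]
        )
        assert float(loss.data) == pytest.approx(total, abs=1e-10)

    def test_empty_batch_error(self, toy_params):
        with pytest.raises(ValueError, match="empty"):
            elbo((np.zeros((0, 6)), np.zeros(0), np.zeros(0)), toy_params)


class TestTrain:
    def test_seeded_trace_reproducible(self, tiny_sim, tiny_cfg):
        p1, t1 = train(tiny_sim.dataset, tiny_cfg, seed=3)
        p2, t2 = train(tiny_sim.dataset, tiny_cfg, seed=3)
        assert t1.train_loss == t2.train_loss
        assert t1.val_loss == t2.val_loss
        for a, b in zip(p1.parameters, p2.parameters):
            np.testing.assert_array_equal(a.data, b.data)

    def test_split_sizes_70_10_20(self, tiny_cfg):
        rng = np.random.default_rng(0)
        ds = CausalDataset(
            (rng.random((100, 4)) < 0.4).astype(int),
            (rng.random(100) < 0.5).astype(int),
            rng.normal(size=100),
        )
        _, trace = train(ds, tiny_cfg, seed=0)
        assert len(trace.train_idx) == 70
        assert len(trace.val_idx) == 10
        assert len(trace.test_idx) == 20
        all_idx = np.concatenate([trace.train_idx, trace.val_idx, trace.test_idx])
        assert sorted(all_idx) == list(range(100))

    def test_loss_decreases_across_seeds(self, tiny_sim):
        cfg = RunConfig(
            latent_dim=2, hidden_width=8, hidden_depth=2, epochs=15,
            patience=15, batch_size=64, n_replicates=1,
        )
        wins = 0
        for seed in range(10):
            _, trace = train(tiny_sim.dataset, cfg, seed=seed)
            wins += trace.train_loss[-1] <= trace.train_loss[0]
        assert wins >= 9

    def test_single_arm_training_split_error(self, tiny_cfg):
        rng = np.random.default_rng(0)
        m = np.zeros(60, dtype=int)
        m[:2] = 1  # so few treated that a split can lose the arm
        # force the treated samples into the test split by trying seeds
        ds = CausalDataset(
            (rng.random((60, 4)) < 0.4).astype(int), m, rng.normal(size=60)
        )
        raised = False
        for seed in range(40):
            try:
                train(ds, tiny_cfg, seed=seed)
            except ValueError as exc:
                assert "single treatment arm" in str(exc)
                raised = True
                break
        assert raised


class TestCounterfactualsAndATE:
    def test_tied_arms_give_exactly_zero_ate(self, tiny_sim, tiny_cfg):
        params = init_model((tiny_sim.dataset.n_confounders, 3), tiny_cfg, seed=0)
        params.tie_outcome_arms()
        y0, y1 = predict_counterfactuals(tiny_sim.dataset, params, n_mc=10, seed=0)
        np.testing.assert_array_equal(y0, y1)
        assert estimate_ate(tiny_sim.dataset, params, n_mc=10, seed=0) == 0.0

    def test_constant_arm_offset_gives_that_ate(self, tiny_sim, tiny_cfg):
        params = init_model((tiny_sim.dataset.n_confounders, 3), tiny_cfg, seed=0)
        params.tie_outcome_arms()
        c = 0.73
        params.py1_net.biases[-1].data = params.py1_net.biases[-1].data + c
        assert estimate_ate(tiny_sim.dataset, params, n_mc=10, seed=0) == pytest.approx(
            c, abs=1e-12
        )

    def test_seeded_prediction_reproducible(self, tiny_sim, tiny_cfg):
        params = init_model((tiny_sim.dataset.n_confounders, 3), tiny_cfg, seed=1)
        a = predict_counterfactuals(tiny_sim.dataset, params, n_mc=1, seed=5)
        b = predict_counterfactuals(tiny_sim.dataset, params, n_mc=1, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_mc_convergence_rate(self, tiny_sim, tiny_cfg):
        """Per-sample predictions converge to a high-draw reference with
        variance shrinking like 1/n_mc."""
        params = init_model((tiny_sim.dataset.n_confounders, 3), tiny_cfg, seed=2)
        ref0, ref1 = predict_counterfactuals(tiny_sim.dataset, params, n_mc=100_000, seed=99)
        errs = {}
        for n_mc in (10, 1000):
            reps = []
            for rep in range(8):
                y0, _ = predict_counterfactuals(
                    tiny_sim.dataset, params, n_mc=n_mc, seed=1000 + rep
                )
                reps.append(((y0 - ref0) ** 2).mean())
            errs[n_mc] = np.mean(reps)
        # 100x more draws should cut squared error by far more than 10x
        assert errs[1000] < errs[10] / 10

    def test_ate_invariant_to_sample_permutation(self, tiny_sim, tiny_cfg):
        params, _ = train(tiny_sim.dataset, tiny_cfg, seed=0)
        ds = tiny_sim.dataset
        perm = np.random.default_rng(8).permutation(ds.n_samples)
        permuted = CausalDataset(ds.X[perm], ds.M[perm], ds.Y[perm])
        a = estimate_ate(ds, params, n_mc=4000, seed=0)
        b = estimate_ate(permuted, params, n_mc=4000, seed=0)
        assert a == pytest.approx(b, abs=0.02)

    def test_infer_from_x_route_runs(self, tiny_sim, tiny_cfg):
        params, _ = train(tiny_sim.dataset, tiny_cfg, seed=0)
        y0, y1 = predict_counterfactuals(
            tiny_sim.dataset, params, n_mc=5, seed=0, infer_from="x"
        )
        assert np.all(np.isfinite(y0)) and np.all(np.isfinite(y1))
        with pytest.raises(ValueError, match="infer_from"):
            predict_counterfactuals(tiny_sim.dataset, params, infer_from="bogus")


class TestRunReplicates:
    def test_single_replicate_std_zero_with_warning(self, tiny_sim, tiny_cfg, caplog):
        cfg = RunConfig(**{**tiny_cfg.to_dict(), "split_fractions": (0.7, 0.1, 0.2),
                           "n_replicates": 1})
        with caplog.at_level("WARNING"):
            est = run_replicates(tiny_sim.dataset, cfg)
        assert est.ate_std == 0.0
        assert len(est.per_replicate) == 1
        assert any("single replicate" in r.message for r in caplog.records)

    def test_reproducible_and_arithmetically_consistent(self, tiny_sim, tiny_cfg):
        est1 = run_replicates(tiny_sim.dataset, tiny_cfg)
        est2 = run_replicates(tiny_sim.dataset, tiny_cfg)
        np.testing.assert_array_equal(est1.per_replicate, est2.per_replicate)
        assert est1.ate_mean == pytest.approx(est1.per_replicate.mean(), abs=1e-12)
        assert est1.ate_std == pytest.approx(est1.per_replicate.std(ddof=1), abs=1e-12)


class TestCEVAEEstimator:
    def test_sklearn_surface_and_fit(self, tiny_sim):
        est = CEVAE(
            latent_dim=2, hidden_width=8, hidden_depth=2, epochs=5, patience=5,
            batch_size=64, n_mc_samples=10, random_state=0,
        )
        params = est.get_params()
        assert params["latent_dim"] == 2
        est.set_params(epochs=6)
        assert est.epochs == 6
        est.fit(tiny_sim.dataset)
        assert hasattr(est, "ate_") and np.isfinite(est.ate_)
        assert est.n_features_in_ == tiny_sim.dataset.n_confounders
        y0, y1 = est.predict_counterfactuals(tiny_sim.dataset)
        assert est.estimate_ate(tiny_sim.dataset) == pytest.approx((y1 - y0).mean())

    def test_unfitted_raises(self, tiny_sim):
        with pytest.raises(RuntimeError, match="not fitted"):
            CEVAE().estimate_ate(tiny_sim.dataset)
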