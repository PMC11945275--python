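"""Driver-model losses, sampling, training and persistence."""

import numpy as np
import pytest
from scipy import stats as sps

from duincoder import (CategoricalPriorVAE, LatentGaussian, anneal_weight,
                       gaussian_log_density, gumbel_softmax, loss_gauss,
                       loss_recon, total_loss)
from duincoder.driver_model import train as train_model
from duincoder.records import WindowBatch

from conftest import build_untrained


class TestGaussianLogDensity:
    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 3, 1000)
        mu = rng.normal(0, 3, 1000)
        var = rng.uniform(0.01, 9.0, 1000)
        per, total = gaussian_log_density(x, mu, var)
        oracle = sps.norm.logpdf(x, loc=mu, scale=np.sqrt(var))
        np.testing.assert_allclose(per, oracle, atol=1e-9)
        assert total == pytest.approx(oracle.sum(), abs=1e-6)

    @pytest.mark.parametrize("x,mu,var,expected", [
        (0.0, 0.0, 1.0, -0.9189385),
        (1.0, 0.0, 1.0, -1.4189385),
        (2.0, 1.0, 4.0, -1.7370858),
    ])
    def test_worked_examples(self, x, mu, var, expected):
        per, _ = gaussian_log_density(x, mu, var)
        assert per == pytest.approx(expected, abs=1e-6)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            gaussian_log_density(0.0, 0.0, 0.0)


class TestLossRecon:
    def test_examples(self):
        x = np.array([[0.0, 2.0]])
        assert loss_recon(x, x) == 0.0
        assert loss_recon(x, np.array([[1.0, 1.0]])) == pytest.approx(1.0)
        assert loss_recon(np.zeros((3, 4)), np.full((3, 4), -1.0)) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            loss_recon(np.zeros((2, 3)), np.zeros((2, 4)))


class TestLossGauss:
    def test_zero_when_prior_equals_posterior(self):
        rng = np.random.default_rng(1)
        g = LatentGaussian(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
        z = rng.normal(size=(5, 3))
        assert loss_gauss(z, g, g) == pytest.approx(0.0, abs=1e-12)

    def test_half_nat_example(self):
        post = LatentGaussian(np.zeros((1, 1)), np.zeros((1, 1)))
        prior = LatentGaussian(np.zeros((1, 1)), np.ones((1, 1)))
        assert loss_gauss(np.zeros((1, 1)), post, prior) == \
            pytest.approx(0.5, abs=1e-9)

    def test_expectation_matches_analytic_kl(self):
        rng = np.random.default_rng(2)
        mu_q, lv_q = 0.7, np.log(0.5)
        mu_p, lv_p = -0.3, np.log(2.0)
        post = LatentGaussian(np.full((1, 1), mu_q), np.full((1, 1), lv_q))
        prior = LatentGaussian(np.full((1, 1), mu_p), np.full((1, 1), lv_p))
        n = 20000
        z = mu_q + np.sqrt(np.exp(lv_q)) * rng.standard_normal(n)
        draws = np.array([loss_gauss(np.array([[zi]]), post, prior)
                          for zi in z[:2000]])
        kl = 0.5 * (lv_p - lv_q + (np.exp(lv_q) + (mu_q - mu_p) ** 2)
                    / np.exp(lv_p) - 1.0)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - kl) < 3 * se


class TestAnnealAndTotal:
    @pytest.mark.parametrize("epoch,period,expected",
                             [(0, 200, 0.0), (100, 200, 1.0), (200, 200, 0.0),
                              (50, 200, 0.5)])
    def test_raised_cosine_cycle(self, epoch, period, expected):
        assert anneal_weight(epoch, period) == pytest.approx(expected, abs=1e-12)

    def test_variant_combination(self):
        assert total_loss("R", 0.3, 5.0) == 0.3
        assert total_loss("G", 0.3, 0.2, w=1.0) == pytest.approx(0.5)
        assert total_loss("G", 0.3, 9.9, w=0.0) == pytest.approx(0.3)
        with pytest.raises(ValueError):
            total_loss("X", 1.0, 1.0)


class TestGumbelSoftmax:
    def test_hard_mode_one_hot(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(50, 8))
        y = gumbel_softmax(logits, 1.0, rng, hard=True)
        assert set(np.unique(y)) == {0.0, 1.0}
        np.testing.assert_array_equal(y.sum(axis=1), 1.0)

    def test_soft_rows_on_simplex(self):
        rng = np.random.default_rng(0)
        y = gumbel_softmax(rng.normal(size=(20, 5)), 0.5, rng)
        assert (y >= 0).all()
        np.testing.assert_allclose(y.sum(axis=1), 1.0, atol=1e-6)

    def test_high_temperature_approaches_uniform(self):
        rng = np.random.default_rng(42)
        logits = np.tile(np.array([[2.0, -1.0, 0.5, 0.0]]), (1000, 1))
        y = gumbel_softmax(logits, 100.0, rng)
        np.testing.assert_allclose(y.mean(axis=0), 0.25, atol=0.05)

    def test_determinism(self):
        logits = np.ones((4, 3))
        a = gumbel_softmax(logits, 1.0, np.random.default_rng(9))
        b = gumbel_softmax(logits, 1.0, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestForwardPieces:
    def test_reparameterize_statistics_and_determinism(self):
        g = LatentGaussian(np.zeros((10000, 2)), np.zeros((10000, 2)))
        z = CategoricalPriorVAE.reparameterize(g, np.random.default_rng(0))
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=0.05)
        z2 = CategoricalPriorVAE.reparameterize(g, np.random.default_rng(0))
        np.testing.assert_array_equal(z, z2)

    def test_reparameterize_zero_noise_limit(self):
        mu = np.array([[1.0, -2.0]])
        g = LatentGaussian(mu, np.full((1, 2), -80.0))
        z = CategoricalPriorVAE.reparameterize(g, np.random.default_rng(0))
        np.testing.assert_allclose(z, mu, atol=1e-8)

    def test_prior_head_zero_init_is_standard_normal(self):
        m = build_untrained()
        y = np.eye(4)
        prior = m.prior_from_categorical(y)
        np.testing.assert_array_equal(prior.mu, 0.0)
        np.testing.assert_array_equal(prior.log_var, 0.0)

    def test_prior_pure_function_of_code(self):
        m = build_untrained()
        m._prior.W[...] = np.random.default_rng(1).normal(
            0, 0.5, m._prior.W.shape)
        y = np.tile(np.eye(4)[0], (3, 1))
        p = m.prior_from_categorical(y)
        assert np.ptp(p.mu, axis=0).max() == 0.0
        p2 = m.prior_from_categorical(np.eye(4)[:2])
        assert not np.allclose(p2.mu[0], p2.mu[1])

    def test_encode_shapes_and_row_equivariance(self):
        m = build_untrained()
        rng = np.random.default_rng(3)
        x = rng.normal(size=(5, 6 * 21))
        y = np.eye(4)[rng.integers(0, 4, 5)]
        g = m.encode(x, y)
        assert g.mu.shape == (5, 8)
        perm = np.array([4, 2, 0, 1, 3])
        gp = m.encode(x[perm], y[perm])
        np.testing.assert_allclose(gp.mu, g.mu[perm], atol=1e-12)
        with pytest.raises(ValueError):
            m.encode(x[:, :-1], y)

    def test_decode_shape_contract(self):
        m = build_untrained()
        z = np.random.default_rng(0).normal(size=(4, 8))
        x_hat = m.decode(z)
        assert x_hat.shape == (4, 6 * 21)
        np.testing.assert_array_equal(m.decode(z[[0, 0]])[0],
                                      m.decode(z[[0, 0]])[1])

    def test_central_span_crop(self):
        m = build_untrained(recon_frames=5)
        x = np.arange(6 * 21, dtype=float)[None, :]
        c = m.central_span(x).reshape(6, 5)
        np.testing.assert_array_equal(c[0], np.arange(8, 13))


class TestValidate:
    def test_k1_equals_single_sample_and_monotone_in_k(self):
        m = build_untrained()
        X = np.random.default_rng(7).normal(size=(30, 6 * 21))
        s1 = m.validate(X, 1, np.random.default_rng(5))
        x_hat = m.sample_reconstruction(X, np.random.default_rng(5))
        direct = np.abs(m.central_span(X) - x_hat).mean(axis=1).mean()
        assert s1 == pytest.approx(direct, abs=1e-12)
        s8 = m.validate(X, 8, np.random.default_rng(5))
        assert s8 <= s1 + 1e-12


class TestTraining:
    def test_smoke_run_and_bitwise_determinism(self, tiny_trained):
        model, stats, batch = tiny_trained
        assert np.isfinite(model.best_validation_score_)
        m2 = CategoricalPriorVAE(**model.get_params())
        m2.fit(batch.data[::4])
        for a, b in zip(model._params(), m2._params()):
            np.testing.assert_array_equal(a, b)

    def test_loss_decreases_variant_r(self):
        rng = np.random.default_rng(0)
        X = np.sin(np.linspace(0, 6, 6 * 21))[None, :] \
            + 0.1 * rng.normal(size=(50, 6 * 21))
        m = build_untrained().set_params(epochs=120, lr0=2e-3)
        m.fit(X)
        hist = m.history_
        assert hist[-1]["lrecon"] < hist[0]["lrecon"]

    def test_drunk_training_data_refused(self):
        X = np.zeros((4, 6 * 21))
        batch = WindowBatch(data=X, center_frames=np.arange(4),
                            record_ids=np.array(["a"] * 4, dtype=object),
                            window_frames=21,
                            labels=np.array(["normal", "drunk"] * 2,
                                            dtype=object))
        with pytest.raises(ValueError, match="normal"):
            train_model(batch, None, CategoricalPriorVAE(window_frames=21))

    def test_checkpoint_roundtrip_bit_exact(self, tiny_trained, tmp_path):
        model, _, batch = tiny_trained
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = CategoricalPriorVAE.load(path)
        assert loaded.best_validation_score_ == model.best_validation_score_
        X = batch.data[:16]
        a = model.sample_reconstruction(X, np.random.default_rng(11))
        b = loaded.sample_reconstruction(X, np.random.default_rng(11))
        np.testing.assert_array_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CategoricalPriorVAE(window_frames=20).fit(np.zeros((2, 120)))
        with pytest.raises(ValueError):
            CategoricalPriorVAE(window_frames=21, variant="Q").fit(
                np.zeros((2, 126)))
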