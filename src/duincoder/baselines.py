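"""Plain Gaussian-prior VAE baseline.

A standard VAE (symmetric encoder/decoder, standard-normal prior) trained on
normal windows, paired with the same minimum-deviation + isolation-forest
detection stage as the main method. Shipped defaults follow the reference
baseline configuration (encoder widths (64, 128, 256, 512, 1024), latent
dimension 2048, Adam lr 0.004 with step decay 0.95 per 50 epochs,
contamination 0.01); tests and desk-scale runs override them downward.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._nn import MLP, Adam, zero_grads
from .driver_model import LV_MAX, LV_MIN
from .records import WindowBatch


class GaussianVAE(BaseEstimator):
    """Fixed standard-normal prior VAE with L1 reconstruction loss."""

    def __init__(self, en_layers=(64, 128, 256, 512, 1024), latent_dim=2048,
                 epochs=100, lr0=0.004, lr_decay=0.95, lr_step_epochs=50,
                 batch_size=256, random_state=0):
        self.en_layers = en_layers
        self.latent_dim = latent_dim
        self.epochs = epochs
        self.lr0 = lr0
        self.lr_decay = lr_decay
        self.lr_step_epochs = lr_step_epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        d_in = X.shape[1]
        ss = np.random.SeedSequence(self.random_state)
        init_ss, loop_ss = ss.spawn(2)
        init = np.random.default_rng(init_ss)
        rng = np.random.default_rng(loop_ss)
        self._enc = MLP([d_in, *self.en_layers, 2 * self.latent_dim], init)
        self._dec = MLP([self.latent_dim, *self.en_layers[::-1], d_in], init)
        params = self._enc.params() + self._dec.params()
        grads = self._enc.grads() + self._dec.grads()
        opt = Adam(params, lr=self.lr0)
        n = X.shape[0]
        for epoch in range(self.epochs):
            opt.lr = self.lr0 * self.lr_decay ** (epoch // self.lr_step_epochs)
            perm = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                xb = X[perm[start:start + self.batch_size]]
                zero_grads(grads)
                q = self._enc.forward(xb, train=True)
                mu, lv_raw = np.split(q, 2, axis=1)
                lv = np.clip(lv_raw, LV_MIN, LV_MAX)
                eps = rng.standard_normal(mu.shape)
                sigma = np.exp(0.5 * lv)
                z = mu + sigma * eps
                x_hat = self._dec.forward(z, train=True)
                B = xb.shape[0]
                # L1 recon + analytic KL(q || N(0, I))
                g_xhat = np.sign(x_hat - xb) / x_hat.size
                g_z = self._dec.backward(g_xhat)
                g_mu = g_z + mu / B
                g_lv = (g_z * eps * 0.5 * sigma
                        + 0.5 * (np.exp(lv) - 1.0) / B)
                g_lv = np.where((lv_raw > LV_MIN) & (lv_raw < LV_MAX),
                                g_lv, 0.0)
                self._enc.backward(np.concatenate([g_mu, g_lv], axis=1))
                opt.step(grads)
        self.n_features_in_ = d_in
        self._rng_infer_seed = ss
        return self

    def sample_reconstruction(self, x: np.ndarray,
                              rng: np.random.Generator) -> np.ndarray:
        q = self._enc.forward(np.asarray(x, dtype=float))
        mu, lv = np.split(q, 2, axis=1)
        lv = np.clip(lv, LV_MIN, LV_MAX)
        z = mu + np.exp(0.5 * lv) * rng.standard_normal(mu.shape)
        return self._dec.forward(z)


def vae_frame_flags(train: WindowBatch, test: WindowBatch, seed: int = 0,
                    k_infer: int = 32, contamination: float = 0.01,
                    **vae_params) -> np.ndarray:
    """Train the VAE baseline on normal windows; flag test frames via
    minimum deviation + isolation forest."""
    from .detector import DeviationIsolationForest

    vae = GaussianVAE(random_state=seed, **vae_params)
    vae.fit(train.data)

    def _dev(batch: WindowBatch, salt: int) -> np.ndarray:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(salt,)))
        L = batch.window_frames
        B = batch.n_windows
        n_ch = batch.n_channels
        best = np.full((B, n_ch), np.inf)
        for _ in range(k_infer):
            x_hat = vae.sample_reconstruction(batch.data, rng)
            err = np.abs(batch.data - x_hat).reshape(B, n_ch, L)
            best = np.minimum(best, err.mean(axis=2))
        return best

    det = DeviationIsolationForest(contamination=contamination,
                                   random_state=seed)
    det.fit(_dev(train, 1))
    return det.predict(_dev(test, 2))
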