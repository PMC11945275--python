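"""Generative driver model: a categorical-prior variational autoencoder.

The model learns what *normal* driving looks like. A flattened, z-scored
window ``x`` of shape (B, N*L) passes through:

1. ``MLPcat`` (LeakyReLU stack) + a combining linear layer → categorical
   logits; a Gumbel-Softmax layer samples a categorical code ``y`` of shape
   (B, Ncat). The code selects, through an affine prior head, a per-category
   latent prior N(mu_y, sigma_y^2).
2. The encoder ``MLPen`` maps [x, y] to the posterior N(mu_z, sigma_z^2);
   reparameterization draws z = mu_z + sigma_z * eps.
3. The decoder ``MLPde`` maps z to a reconstruction ``x_hat`` over the
   central L' frames of the window.

Training minimizes L = Lrecon + w * Lgauss, where Lrecon is the mean L1
distance between the central span and its reconstruction, Lgauss is a
single-sample estimate of the posterior-vs-prior log-density gap
(log p(z|mu_z,sigma_z^2) - log p(z|mu_y,sigma_y^2)), and w is a raised-cosine
cyclical annealing weight. Variant "G" uses both terms; variant "R" trains on
the reconstruction loss alone (the stricter detector of the two).

Networks, gradients and the Adam updates are implemented directly on numpy
arrays (see ``_nn``); runs are bit-reproducible from ``random_state``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from ._nn import MLP, Adam, Linear, load_params, zero_grads
from .records import WindowBatch

LOG_2PI = float(np.log(2.0 * np.pi))
# log-variance clamp: lower bound enforces the 1e-8 variance floor
LV_MIN, LV_MAX = np.log(1e-8), 8.0

CHECKPOINT_SCHEMA = 1


class NumericalError(FloatingPointError):
    """Training produced a non-finite loss or activation."""


@dataclass
class LatentGaussian:
    """Diagonal Gaussian over the latent space, parameterized by log-variance."""

    mu: np.ndarray
    log_var: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.log_var = np.asarray(self.log_var, dtype=float)
        if not np.isfinite(self.log_var).all():
            raise ValueError("log_var must be finite")


# ---------------------------------------------------------------------------
# Loss primitives


def gaussian_log_density(x, mu, var):
    """Elementwise log N(x | mu, var) and its total.

    Returns ``(per_element, total)`` with
    per_element = -0.5 * (log 2*pi + log var + (x - mu)^2 / var).
    """
    x, mu, var = np.asarray(x, float), np.asarray(mu, float), np.asarray(var, float)
    if np.any(var <= 0):
        raise ValueError("variance must be strictly positive")
    per = -0.5 * (LOG_2PI + np.log(var) + (x - mu) ** 2 / var)
    return per, float(per.sum())


def loss_recon(x_central: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean absolute (L1) deviation over the central reconstruction span."""
    if x_central.shape != x_hat.shape:
        raise ValueError(
            f"shape mismatch: {x_central.shape} vs {x_hat.shape}")
    return float(np.mean(np.abs(x_central - x_hat)))


def loss_gauss(z: np.ndarray, posterior: LatentGaussian,
               prior: LatentGaussian) -> float:
    """Single-sample Monte-Carlo posterior-vs-prior log-density gap.

    Sum over latent dimensions of log p(z|posterior) - log p(z|prior),
    averaged over the batch; its expectation over z ~ posterior is the
    Gaussian KL divergence.
    """
    z = np.asarray(z, float)
    post_per, _ = gaussian_log_density(z, posterior.mu, np.exp(posterior.log_var))
    prior_per, _ = gaussian_log_density(z, prior.mu, np.exp(prior.log_var))
    return float((post_per - prior_per).sum(axis=-1).mean())


def anneal_weight(epoch: int, period: int) -> float:
    """Cyclical raised-cosine weight: 0 at cycle start, 1 at mid-cycle."""
    if period < 1:
        raise ValueError("period must be >= 1")
    return 0.5 * (1.0 - float(np.cos(2.0 * np.pi * (epoch % period) / period)))


def total_loss(variant: str, lrecon: float, lgauss: float, w: float = 1.0) -> float:
    """Variant G: lrecon + w * lgauss. Variant R: lrecon only."""
    if variant == "R":
        return lrecon
    if variant == "G":
        return lrecon + w * lgauss
    raise ValueError(f"unknown variant {variant!r}")


def _softmax(s: np.ndarray) -> np.ndarray:
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


def gumbel_softmax(logits: np.ndarray, temperature: float,
                   rng: np.random.Generator, hard: bool = False) -> np.ndarray:
    """Sample a (relaxed) categorical code from logits.

    Soft mode returns softmax((logits + Gumbel noise) / temperature); hard
    mode returns the exact one-hot argmax of the perturbed logits.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    g = rng.gumbel(size=logits.shape)
    s = (logits + g) / temperature
    if hard:
        y = np.zeros_like(logits)
        y[np.arange(logits.shape[0]), s.argmax(axis=1)] = 1.0
        return y
    return _softmax(s)


# ---------------------------------------------------------------------------
# Estimator


class CategoricalPriorVAE(BaseEstimator):
    """Driver model with a Gumbel-Softmax categorical latent prior.

    Parameters
    ----------
    n_channels : number of telemetry channels N (6).
    window_frames : input window length L (odd).
    recon_frames : reconstruction span L' (odd, <= L); None means L.
    n_categories : size of the categorical code (Ncat).
    latent_dim : dimension of z.
    hidden_cat, hidden_en, hidden_de : hidden layer widths of the three MLPs.
    gumbel_temperature : Gumbel-Softmax temperature (soft samples in training,
        hard one-hot at inference).
    variant : "G" (reconstruction + annealed ELBO) or "R" (reconstruction only).
    epochs, lr0, lr_decay, lr_step_epochs : Adam schedule; the learning rate
        is lr0 * lr_decay ** (epoch // lr_step_epochs).
    anneal_period_epochs : period of the cyclical cosine weight on Lgauss.
    val_interval_epochs, k_val : validation cadence and sample count for
        checkpoint selection (lowest mean minimum deviation wins; earliest
        epoch breaks ties).
    batch_size : minibatch size; per-epoch reshuffle from the run seed.
    random_state : seed for init, shuffling, and all latent sampling.
    """

    def __init__(self, n_channels=6, window_frames=101, recon_frames=None,
                 n_categories=16, latent_dim=64, hidden_cat=(512, 256),
                 hidden_en=(512, 256), hidden_de=(256, 512),
                 gumbel_temperature=1.0, variant="R", epochs=2000,
                 lr0=4e-4, lr_decay=0.95, lr_step_epochs=50,
                 anneal_period_epochs=200, val_interval_epochs=20, k_val=32,
                 batch_size=256, random_state=0):
        self.n_channels = n_channels
        self.window_frames = window_frames
        self.recon_frames = recon_frames
        self.n_categories = n_categories
        self.latent_dim = latent_dim
        self.hidden_cat = hidden_cat
        self.hidden_en = hidden_en
        self.hidden_de = hidden_de
        self.gumbel_temperature = gumbel_temperature
        self.variant = variant
        self.epochs = epochs
        self.lr0 = lr0
        self.lr_decay = lr_decay
        self.lr_step_epochs = lr_step_epochs
        self.anneal_period_epochs = anneal_period_epochs
        self.val_interval_epochs = val_interval_epochs
        self.k_val = k_val
        self.batch_size = batch_size
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    @property
    def _l_prime(self) -> int:
        return self.window_frames if self.recon_frames is None else self.recon_frames

    def _check_config(self) -> None:
        L, Lp = self.window_frames, self._l_prime
        if L % 2 == 0 or L < 1 or Lp % 2 == 0 or Lp < 1 or Lp > L:
            raise ValueError("window_frames and recon_frames must be odd, "
                             "with 1 <= recon_frames <= window_frames")
        if self.n_categories < 2 or self.latent_dim < 1 or self.k_val < 1:
            raise ValueError("n_categories >= 2, latent_dim >= 1, k_val >= 1")
        if self.variant not in ("G", "R"):
            raise ValueError("variant must be 'G' or 'R'")

    def _build(self, seed_seq: np.random.SeedSequence) -> None:
        self._check_config()
        D_in = self.n_channels * self.window_frames
        D_out = self.n_channels * self._l_prime
        init = [np.random.default_rng(s) for s in seed_seq.spawn(4)]
        self._cat = MLP([D_in, *self.hidden_cat], init[0], activate_last=True)
        self._comb = Linear(self.hidden_cat[-1], self.n_categories, init[0])
        self._prior = Linear(self.n_categories, 2 * self.latent_dim, init[1])
        # zero prior head: every category starts at the standard normal
        self._prior.W[...] = 0.0
        self._enc = MLP([D_in + self.n_categories, *self.hidden_en,
                         2 * self.latent_dim], init[2])
        self._dec = MLP([self.latent_dim, *self.hidden_de, D_out], init[3])
        half = (self.window_frames - self._l_prime) // 2
        per_ch = half + np.arange(self._l_prime)
        self._central_idx = (np.arange(self.n_channels)[:, None]
                             * self.window_frames + per_ch[None, :]).ravel()

    def _all_nets(self):
        return [self._cat, self._comb, self._prior, self._enc, self._dec]

    def _params(self):
        return [p for net in self._all_nets() for p in net.params()]

    def _grads(self):
        return [g for net in self._all_nets() for g in net.grads()]

    # -- forward pieces ----------------------------------------------------

    def categorical_head(self, x: np.ndarray, rng: np.random.Generator,
                         hard: bool = False, train: bool = False) -> np.ndarray:
        """x → MLPcat → combining layer → Gumbel-Softmax code y."""
        h = self._cat.forward(x, train=train)
        logits = self._comb.forward(h, train=train)
        if not np.isfinite(logits).all():
            raise NumericalError("non-finite categorical logits")
        return gumbel_softmax(logits, self.gumbel_temperature, rng, hard=hard)

    def prior_from_categorical(self, y: np.ndarray,
                               train: bool = False) -> LatentGaussian:
        p = self._prior.forward(y, train=train)
        mu, lv = np.split(p, 2, axis=1)
        return LatentGaussian(mu, np.clip(lv, LV_MIN, LV_MAX))

    def encode(self, x: np.ndarray, y: np.ndarray,
               train: bool = False) -> LatentGaussian:
        expected = self.n_channels * self.window_frames + self.n_categories
        if x.shape[1] + y.shape[1] != expected:
            raise ValueError(f"encoder input width {x.shape[1] + y.shape[1]} "
                             f"!= expected {expected}")
        q = self._enc.forward(np.concatenate([x, y], axis=1), train=train)
        mu, lv = np.split(q, 2, axis=1)
        return LatentGaussian(mu, np.clip(lv, LV_MIN, LV_MAX))

    @staticmethod
    def reparameterize(g: LatentGaussian, rng: np.random.Generator) -> np.ndarray:
        eps = rng.standard_normal(g.mu.shape)
        return g.mu + np.exp(0.5 * g.log_var) * eps

    def decode(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        return self._dec.forward(z, train=train)

    def central_span(self, x: np.ndarray) -> np.ndarray:
        """The central L' frames of each flattened window (feature-major)."""
        return x[:, self._central_idx]

    def sample_reconstruction(self, x: np.ndarray,
                              rng: np.random.Generator) -> np.ndarray:
        """One full stochastic pass x → y (hard) → posterior → z → x_hat."""
        y = self.categorical_head(x, rng, hard=True)
        post = self.encode(x, y)
        z = self.reparameterize(post, rng)
        return self.decode(z)

    # -- training ----------------------------------------------------------

    def fit(self, X, y=None, X_val=None):
        """Train on normal-driving windows; select the checkpoint with the
        lowest validation minimum-deviation score.

        X and X_val are (B, N*L) arrays of z-scored flattened windows.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_channels * self.window_frames:
            raise ValueError(f"X must be (B, {self.n_channels * self.window_frames})")
        ss = np.random.SeedSequence(self.random_state)
        init_ss, shuffle_s, noise_s, val_s = ss.spawn(4)
        self._build(init_ss)
        shuffle_rng = np.random.default_rng(shuffle_s)
        noise_rng = np.random.default_rng(noise_s)
        self._val_seed = val_s

        params = self._params()
        grads = self._grads()
        opt = Adam(params, lr=self.lr0)
        n = X.shape[0]
        history: list[dict] = []
        best_score, best_epoch, best_snapshot = np.inf, -1, None

        for epoch in range(self.epochs):
            opt.lr = self.lr0 * self.lr_decay ** (epoch // self.lr_step_epochs)
            w = (anneal_weight(epoch, self.anneal_period_epochs)
                 if self.variant == "G" else 0.0)
            perm = shuffle_rng.permutation(n)
            ep_rec, ep_gauss, n_batches = 0.0, 0.0, 0
            for start in range(0, n, self.batch_size):
                xb = X[perm[start:start + self.batch_size]]
                lrec, lgauss = self._train_step(xb, w, opt, grads, noise_rng)
                if not np.isfinite(lrec):
                    raise NumericalError(
                        f"non-finite loss at epoch {epoch}, batch {n_batches}")
                ep_rec += lrec
                ep_gauss += lgauss
                n_batches += 1
            row = {"epoch": epoch, "lrecon": ep_rec / n_batches,
                   "lgauss": ep_gauss / n_batches, "anneal_w": w,
                   "lr": opt.lr, "val_score": np.nan}
            last_epoch = epoch == self.epochs - 1
            if X_val is not None and ((epoch + 1) % self.val_interval_epochs == 0
                                      or last_epoch):
                score = self.validate(X_val, self.k_val,
                                      np.random.default_rng(self._val_seed))
                row["val_score"] = score
                if score < best_score:
                    best_score, best_epoch = score, epoch
                    best_snapshot = [p.copy() for p in params]
            history.append(row)

        if best_snapshot is not None:
            for p, s in zip(params, best_snapshot):
                p[...] = s
            self.best_validation_score_ = float(best_score)
            self.best_epoch_ = best_epoch
        else:
            score = self.validate(X, min(self.k_val, 4),
                                  np.random.default_rng(self._val_seed))
            self.best_validation_score_ = float(score)
            self.best_epoch_ = self.epochs - 1
        self.history_ = history
        self.n_features_in_ = X.shape[1]
        return self

    def _train_step(self, x, w, opt, grads, rng):
        zero_grads(grads)
        B = x.shape[0]
        tau = self.gumbel_temperature
        # forward
        h = self._cat.forward(x, train=True)
        logits = self._comb.forward(h, train=True)
        g = rng.gumbel(size=logits.shape)
        yv = _softmax((logits + g) / tau)
        p = self._prior.forward(yv, train=True)
        mu_y, lv_y_raw = np.split(p, 2, axis=1)
        lv_y = np.clip(lv_y_raw, LV_MIN, LV_MAX)
        q = self._enc.forward(np.concatenate([x, yv], axis=1), train=True)
        mu_z, lv_z_raw = np.split(q, 2, axis=1)
        lv_z = np.clip(lv_z_raw, LV_MIN, LV_MAX)
        eps = rng.standard_normal(mu_z.shape)
        sigma = np.exp(0.5 * lv_z)
        z = mu_z + sigma * eps
        x_hat = self._dec.forward(z, train=True)
        x_c = self.central_span(x)
        lrec = float(np.mean(np.abs(x_c - x_hat)))
        inv_vz = np.exp(-lv_z)
        inv_vy = np.exp(-lv_y)
        dz_post = z - mu_z
        dz_prior = z - mu_y
        lgauss = float((-0.5 * ((lv_z - lv_y)
                                + dz_post ** 2 * inv_vz
                                - dz_prior ** 2 * inv_vy)).sum(axis=1).mean())
        # backward
        g_xhat = np.sign(x_hat - x_c) / x_hat.size
        g_z = self._dec.backward(g_xhat)
        use_gauss = self.variant == "G" and w != 0.0
        if use_gauss:
            g_z = g_z + w * (-dz_post * inv_vz + dz_prior * inv_vy) / B
            g_mu_z_d = w * (dz_post * inv_vz) / B
            g_lv_z_d = w * (-0.5 * (1.0 - dz_post ** 2 * inv_vz)) / B
            g_mu_y = w * (-dz_prior * inv_vy) / B
            g_lv_y = w * (0.5 * (1.0 - dz_prior ** 2 * inv_vy)) / B
        else:
            g_mu_z_d = g_lv_z_d = 0.0
        g_mu_z = g_z + g_mu_z_d
        g_lv_z = g_z * eps * 0.5 * sigma + g_lv_z_d
        g_lv_z = np.where((lv_z_raw > LV_MIN) & (lv_z_raw < LV_MAX), g_lv_z, 0.0)
        g_ein = self._enc.backward(np.concatenate([g_mu_z, g_lv_z], axis=1))
        g_y = g_ein[:, -self.n_categories:].copy()
        if use_gauss:
            g_lv_y = np.where((lv_y_raw > LV_MIN) & (lv_y_raw < LV_MAX),
                              g_lv_y, 0.0)
            g_y += self._prior.backward(
                np.concatenate([g_mu_y, g_lv_y], axis=1))
        g_s = yv * (g_y - (g_y * yv).sum(axis=1, keepdims=True))
        g_h = self._comb.backward(g_s / tau)
        self._cat.backward(g_h)
        opt.step(grads)
        return lrec, lgauss

    # -- validation --------------------------------------------------------

    def validate(self, X, K: int, rng: np.random.Generator,
                 chunk: int = 2048) -> float:
        """Mean over windows of the K-sample minimum mean-|dev| score.

        For each window, K stochastic reconstructions are drawn; the minimum
        over samples of the mean absolute deviation from the central span is
        the window's score.
        """
        if K < 1:
            raise ValueError("K must be >= 1")
        X = np.asarray(X, dtype=float)
        total, n = 0.0, X.shape[0]
        for start in range(0, n, chunk):
            xb = X[start:start + chunk]
            x_c = self.central_span(xb)
            best = np.full(xb.shape[0], np.inf)
            for _ in range(K):
                x_hat = self.sample_reconstruction(xb, rng)
                dev = np.abs(x_c - x_hat).mean(axis=1)
                best = np.minimum(best, dev)
            total += best.sum()
        return float(total / n)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist config, parameters and best validation score to one file."""
        arrays = {f"n{i}_{k}": v
                  for i, net in enumerate(self._all_nets())
                  for k, v in enumerate_params(net)}
        meta = {"schema": CHECKPOINT_SCHEMA, "params": self.get_params(),
                "best_validation_score": getattr(
                    self, "best_validation_score_", None),
                "best_epoch": getattr(self, "best_epoch_", None)}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CategoricalPriorVAE":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            if meta.get("schema") != CHECKPOINT_SCHEMA:
                raise ValueError("unsupported checkpoint schema")
            model = cls(**meta["params"])
            model._build(np.random.SeedSequence(model.random_state))
            for i, net in enumerate(model._all_nets()):
                arrays = {f"p{j}": npz[f"n{i}_p{j}"]
                          for j in range(len(net.params()))}
                load_params(net.params(), arrays)
        if meta["best_validation_score"] is not None:
            model.best_validation_score_ = meta["best_validation_score"]
            model.best_epoch_ = meta["best_epoch"]
        model.n_features_in_ = model.n_channels * model.window_frames
        return model


def enumerate_params(net):
    for j, p in enumerate(net.params()):
        yield f"p{j}", p


def train(train_windows: WindowBatch, val_windows: WindowBatch | None,
          model: CategoricalPriorVAE) -> CategoricalPriorVAE:
    """Fit the driver model on a window batch, enforcing the normal-only
    training contract: any drunk-status window is a hard refusal.
    """
    if train_windows.labels is not None and \
            np.any(train_windows.labels == "drunk"):
        raise ValueError(
            "driver model training requires normal-status records only; "
            "drunk-status windows were supplied")
    X_val = val_windows.data if val_windows is not None else None
    return model.fit(train_windows.data, X_val=X_val)
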