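"""Minimal dense-network primitives: linear layers, LeakyReLU MLPs, Adam.

The driver model needs only fully connected stacks with LeakyReLU
activations, so reverse-mode gradients are written out by hand; parameters
live in plain float64 arrays, which keeps checkpoints portable and forward
passes bit-reproducible.
"""

from __future__ import annotations

import numpy as np

LEAKY_SLOPE = 0.01


class Linear:
    """Dense layer y = x W + b with He-style initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._x is not None, "backward before forward(train=True)"
        self.gW += self._x.T @ gy
        self.gb += gy.sum(axis=0)
        return gy @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


class LeakyReLU:
    def __init__(self, slope: float = LEAKY_SLOPE):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, self.slope * gy)

    def params(self):
        return []

    def grads(self):
        return []


class MLP:
    """Stack of Linear layers, LeakyReLU after every layer except the last.

    ``activate_last`` appends a trailing LeakyReLU (used for feature trunks
    whose output feeds another linear head).
    """

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 activate_last: bool = False):
        self.layers: list = []
        for i in range(len(widths) - 1):
            self.layers.append(Linear(widths[i], widths[i + 1], rng))
            if i < len(widths) - 2 or activate_last:
                self.layers.append(LeakyReLU())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


class Adam:
    """Adam with the standard bias correction; lr settable per step."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def zero_grads(grads: list[np.ndarray]) -> None:
    for g in grads:
        g[...] = 0.0


def flatten_params(params: list[np.ndarray]) -> dict[str, np.ndarray]:
    return {f"p{i}": p for i, p in enumerate(params)}


def load_params(params: list[np.ndarray], arrays: dict[str, np.ndarray]) -> None:
    for i, p in enumerate(params):
        src = arrays[f"p{i}"]
        if src.shape != p.shape:
            raise ValueError(f"checkpoint parameter p{i} shape mismatch: "
                             f"{src.shape} vs {p.shape}")
        p[...] = src
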