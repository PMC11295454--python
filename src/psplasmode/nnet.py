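"""Minimal deterministic feed-forward network engine.

Supports exactly the design features the propensity-score study toggles:
dropout, L2 weight penalty, batch normalization and He-normal kernel
initialization (Glorot-uniform otherwise), trained with Adam on binary
cross-entropy (classifier) or mean squared reconstruction error
(autoencoder).  Everything is seeded through one numpy Generator, so runs
are bit-reproducible on a given machine.
"""

from __future__ import annotations

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9  # running-statistics update weight for inference


class _Layer:
    """Linear -> [batch norm] -> activation -> [dropout] block."""

    def __init__(self, fan_in, fan_out, activation, dropout, batch_norm, he_init, rng):
        if he_init:
            self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))
        else:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W = rng.uniform(-limit, limit, (fan_in, fan_out))
        self.b = np.zeros(fan_out)
        self.activation = activation  # "relu" | "linear"
        self.dropout = dropout
        self.batch_norm = batch_norm
        if batch_norm:
            self.gamma = np.ones(fan_out)
            self.beta = np.zeros(fan_out)
            self.run_mean = np.zeros(fan_out)
            self.run_var = np.ones(fan_out)

    def params(self):
        out = [("W", self.W), ("b", self.b)]
        if self.batch_norm:
            out += [("gamma", self.gamma), ("beta", self.beta)]
        return out

    def forward(self, x, training, rng):
        self._x = x
        z = x @ self.W + self.b
        if self.batch_norm:
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                self.run_mean = _BN_MOMENTUM * self.run_mean + (1 - _BN_MOMENTUM) * mu
                self.run_var = _BN_MOMENTUM * self.run_var + (1 - _BN_MOMENTUM) * var
            else:
                mu, var = self.run_mean, self.run_var
            self._inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            self._xhat = (z - mu) * self._inv_std
            z = self.gamma * self._xhat + self.beta
        if self.activation == "relu":
            self._mask_relu = z > 0
            z = np.where(self._mask_relu, z, 0.0)
        if training and self.dropout > 0:
            keep = rng.random(z.shape) >= self.dropout
            self._mask_drop = keep / (1.0 - self.dropout)
            z = z * self._mask_drop
        else:
            self._mask_drop = None
        return z

    def backward(self, g, l2):
        if self._mask_drop is not None:
            g = g * self._mask_drop
        if self.activation == "relu":
            g = g * self._mask_relu
        if self.batch_norm:
            self._dgamma = (g * self._xhat).sum(axis=0)
            self._dbeta = g.sum(axis=0)
            n = g.shape[0]
            dxhat = g * self.gamma
            g = (
                self._inv_std
                / n
                * (n * dxhat - dxhat.sum(axis=0) - self._xhat * (dxhat * self._xhat).sum(axis=0))
            )
        self._dW = self._x.T @ g + 2.0 * l2 * self.W
        self._db = g.sum(axis=0)
        return g @ self.W.T

    def grads(self):
        out = [self._dW, self._db]
        if self.batch_norm:
            out += [self._dgamma, self._dbeta]
        return out


class FeedForward:
    """Sequential network; ``task`` is "binary" (sigmoid + BCE) or
    "reconstruction" (linear output + MSE)."""

    def __init__(
        self,
        sizes: list[int],
        task: str = "binary",
        dropout: float = 0.0,
        l2: float = 0.0,
        batch_norm: bool = False,
        he_init: bool = False,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ):
        if task not in ("binary", "reconstruction"):
            raise ValueError(f"unknown task {task!r}")
        self.task = task
        self.l2 = l2
        self.lr = learning_rate
        self.rng = np.random.default_rng(seed)
        self.layers = [
            _Layer(
                sizes[i],
                sizes[i + 1],
                activation="relu" if i < len(sizes) - 2 else "linear",
                dropout=dropout if i < len(sizes) - 2 else 0.0,
                batch_norm=batch_norm if i < len(sizes) - 2 else False,
                he_init=he_init,
                rng=self.rng,
            )
            for i in range(len(sizes) - 1)
        ]
        # Adam state
        self._m = [[np.zeros_like(p) for _, p in lay.params()] for lay in self.layers]
        self._v = [[np.zeros_like(p) for _, p in lay.params()] for lay in self.layers]
        self._t = 0

    def _forward(self, X, training):
        h = X
        for lay in self.layers:
            h = lay.forward(h, training, self.rng)
        return h

    def _adam_step(self):
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        corr1 = 1 - b1**self._t
        corr2 = 1 - b2**self._t
        for lay, m_l, v_l in zip(self.layers, self._m, self._v):
            for (name, p), g, m, v in zip(lay.params(), lay.grads(), m_l, v_l):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + eps)

    def fit(self, X, Y, epochs: int = 50, batch_size: int = 64) -> dict:
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n = X.shape[0]
        history = []
        for _ in range(epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = X[idx], Y[idx]
                z = self._forward(xb, training=True)
                if self.task == "binary":
                    p = 1.0 / (1.0 + np.exp(-z))
                    p = np.clip(p, 1e-12, 1 - 1e-12)
                    loss = -np.mean(yb * np.log(p) + (1 - yb) * np.log(1 - p))
                    g = (p - yb) / len(idx)  # fused sigmoid + BCE gradient
                else:
                    diff = z - yb
                    loss = np.mean(diff**2)
                    g = 2.0 * diff / diff.size
                epoch_loss += loss * len(idx)
                for lay in reversed(self.layers):
                    g = lay.backward(g, self.l2)
                self._adam_step()
            history.append(epoch_loss / n)
        converged = bool(np.isfinite(history[-1])) if history else True
        return {"loss": history, "converged": converged}

    def predict(self, X) -> np.ndarray:
        z = self._forward(np.asarray(X, dtype=float), training=False)
        if self.task == "binary":
            return (1.0 / (1.0 + np.exp(-z))).ravel()
        return z

    def hidden(self, X, layer_index: int) -> np.ndarray:
        """Activations after block ``layer_index`` in inference mode (used to
        read the autoencoder bottleneck)."""
        h = np.asarray(X, dtype=float)
        for lay in self.layers[: layer_index + 1]:
            h = lay.forward(h, training=False, rng=self.rng)
        return h
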