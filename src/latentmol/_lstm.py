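"""Single-layer LSTM primitives in NumPy.

Forward/backward passes are batched over sequences (loop over time,
vectorized over the batch).  The layout of the fused gate matrix is
``[input, forget, candidate, output]``.  Gradients are exact analytic BPTT
and are validated against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LSTMCell:
    """LSTM parameters plus forward/backward over padded sequences."""

    n_input: int
    n_hidden: int
    rng: np.random.Generator

    def __post_init__(self) -> None:
        scale = 1.0 / np.sqrt(self.n_hidden)
        self.Wx = self.rng.uniform(-scale, scale,
                                   (self.n_input, 4 * self.n_hidden))
        self.Wh = self.rng.uniform(-scale, scale,
                                   (self.n_hidden, 4 * self.n_hidden))
        self.b = np.zeros(4 * self.n_hidden)
        # forget-gate bias init at 1 stabilizes early training
        self.b[self.n_hidden:2 * self.n_hidden] = 1.0

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def step(self, x: np.ndarray, h: np.ndarray, c: np.ndarray):
        """One time step for a batch; returns (h', c', cache)."""
        z = x @ self.Wx + h @ self.Wh + self.b
        H = self.n_hidden
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        cache = (x, h, c, i, f, g, o, c_new)
        return h_new, c_new, cache

    def forward(self, x_seq: np.ndarray, h0: np.ndarray, c0: np.ndarray):
        """Run a (B, T, n_input) batch; returns (H_seq, h_T, c_T, caches)."""
        B, T, _ = x_seq.shape
        h, c = h0, c0
        hs = np.empty((B, T, self.n_hidden))
        caches = []
        for t in range(T):
            h, c, cache = self.step(x_seq[:, t, :], h, c)
            hs[:, t, :] = h
            caches.append(cache)
        return hs, h, c, caches

    def backward(self, caches, d_hs: np.ndarray | None,
                 dh_last: np.ndarray, dc_last: np.ndarray):
        """BPTT through a forward pass.

        ``d_hs`` holds per-step gradients w.r.t. the emitted hidden states
        (may be None), ``dh_last``/``dc_last`` the gradient flowing into the
        final state.  Returns (grads, dh0, dc0) where grads matches
        :attr:`params`.
        """
        H = self.n_hidden
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dh, dc = dh_last.copy(), dc_last.copy()
        for t in range(len(caches) - 1, -1, -1):
            if d_hs is not None:
                dh = dh + d_hs[:, t, :]
            x, h_prev, c_prev, i, f, g, o, c_new = caches[t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dWx += x.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh = dz @ self.Wh.T
            dc = dc * f
        return [dWx, dWh, db], dh, dc


@dataclass
class Dense:
    """Affine projection to per-character logits."""

    n_input: int
    n_output: int
    rng: np.random.Generator

    def __post_init__(self) -> None:
        scale = 1.0 / np.sqrt(self.n_input)
        self.W = self.rng.uniform(-scale, scale, (self.n_input, self.n_output))
        self.b = np.zeros(self.n_output)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, h: np.ndarray) -> np.ndarray:
        return h @ self.W + self.b

    def backward(self, h: np.ndarray, d_logits: np.ndarray):
        """h: (..., n_input); d_logits matching.  Returns (grads, dh)."""
        h2 = h.reshape(-1, self.n_input)
        d2 = d_logits.reshape(-1, self.n_output)
        dW = h2.T @ d2
        db = d2.sum(axis=0)
        dh = d_logits @ self.W.T
        return [dW, db], dh


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean categorical cross-entropy; ``targets`` is one-hot like probs."""
    eps = 1e-12
    per_pos = -(targets * np.log(probs + eps)).sum(axis=-1)
    return float(per_pos.mean())


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray],
             clip_norm: float | None = 5.0) -> None:
        if clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if total > clip_norm:
                grads = [g * (clip_norm / total) for g in grads]
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[:] = self.beta1 * m + (1 - self.beta1) * g
            v[:] = self.beta2 * v + (1 - self.beta2) * g ** 2
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
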