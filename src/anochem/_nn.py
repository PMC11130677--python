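"""Minimal fully-connected neural network on NumPy.

Shared engine for the fingerprint autoencoder and the feed-forward
classifier: ReLU hidden layers, sigmoid outputs, per-output binary
cross-entropy, inverted dropout, Adam updates. Everything is float32 and
seeded through a ``numpy.random.Generator``; early stopping is the
caller's job (see :func:`MLP.state_dict` / :func:`MLP.load_state_dict`).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

_EPS = 1e-7


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binary cross-entropy over all samples and output units."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class MLP:
    """Dense net ``sizes[0] -> ... -> sizes[-1]`` with sigmoid outputs.

    Parameters
    ----------
    sizes
        Layer widths including input and output dimension.
    dropout
        Inverted-dropout rate applied to hidden activations during
        training only.
    seed
        Seeds weight initialization (He for ReLU layers).
    """

    def __init__(self, sizes: Sequence[int], dropout: float = 0.0, seed: int = 0):
        if len(sizes) < 2 or any(s <= 0 for s in sizes):
            raise ValueError(f"invalid layer sizes: {sizes}")
        if not 0.0 <= dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1): {dropout}")
        self.sizes = tuple(int(s) for s in sizes)
        self.dropout = float(dropout)
        rng = np.random.default_rng(seed)
        self.Ws: list[np.ndarray] = []
        self.bs: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.Ws.append(rng.standard_normal((fan_in, fan_out)).astype(np.float32) * scale)
            self.bs.append(np.zeros(fan_out, dtype=np.float32))
        # Adam state
        self._m = [np.zeros_like(w) for w in self.Ws + self.bs]
        self._v = [np.zeros_like(w) for w in self.Ws + self.bs]
        self._t = 0

    # ------------------------------------------------------------------ io
    def state_dict(self) -> dict[str, np.ndarray]:
        d: dict[str, np.ndarray] = {}
        for i, (w, b) in enumerate(zip(self.Ws, self.bs)):
            d[f"W{i}"] = w.copy()
            d[f"b{i}"] = b.copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for i in range(len(self.Ws)):
            self.Ws[i] = np.asarray(d[f"W{i}"], dtype=np.float32).copy()
            self.bs[i] = np.asarray(d[f"b{i}"], dtype=np.float32).copy()

    # ------------------------------------------------------------- forward
    def predict(self, X: np.ndarray) -> np.ndarray:
        A = np.asarray(X, dtype=np.float32)
        last = len(self.Ws) - 1
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            Z = A @ W + b
            A = sigmoid(Z) if i == last else np.maximum(Z, 0.0)
        return A

    def loss(self, X: np.ndarray, Y: np.ndarray) -> float:
        return bce(np.asarray(Y, dtype=np.float32), self.predict(X))

    # ------------------------------------------------------------ training
    def fit_epoch(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        lr: float,
        batch_size: int,
        rng: np.random.Generator,
    ) -> float:
        """One shuffled pass of minibatch Adam; returns mean training BCE."""
        X = np.asarray(X, dtype=np.float32)
        Y = np.asarray(Y, dtype=np.float32)
        n = X.shape[0]
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            total += self._step(X[idx], Y[idx], lr, rng) * len(idx)
        return total / n

    def _step(self, Xb, Yb, lr, rng) -> float:
        last = len(self.Ws) - 1
        A = Xb
        acts = [A]  # inputs to each layer
        masks: list[np.ndarray | None] = []
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            Z = A @ W + b
            if i == last:
                A = sigmoid(Z)
                masks.append(None)
            else:
                A = np.maximum(Z, 0.0)
                if self.dropout > 0.0:
                    keep = 1.0 - self.dropout
                    mask = (rng.random(A.shape) < keep).astype(np.float32) / keep
                    A = A * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            acts.append(A)
        out = acts[-1]
        loss = bce(Yb, out)

        m, d_out = Yb.shape[0], Yb.shape[1]
        delta = (out - Yb) / np.float32(m * d_out)  # dL/dZ_last for sigmoid+BCE
        grads_W: list[np.ndarray] = [None] * len(self.Ws)  # type: ignore[list-item]
        grads_b: list[np.ndarray] = [None] * len(self.bs)  # type: ignore[list-item]
        for i in range(last, -1, -1):
            grads_W[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.Ws[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (acts[i] > 0.0)
        self._adam(grads_W + grads_b, lr)
        return loss

    def _adam(self, grads: list[np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self._t += 1
        params = self.Ws + self.bs
        bc1 = 1.0 - b1**self._t
        bc2 = 1.0 - b2**self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * np.square(g)
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)
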