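"""Minimal 1-D convolutional regression network in numpy.

Forward/backward passes are written with im2col matrix products so the whole
net runs on BLAS; optimisation is Adam on mean-squared error with a sigmoid
output head.  Deliberately small: two conv blocks, global average pooling,
one dense hidden layer.  Deterministic given the construction seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvNet1D"]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class ConvNet1D:
    """conv(k)->relu->avgpool2 -> conv(k)->relu->avgpool2 -> GAP -> dense -> sigmoid."""

    def __init__(
        self,
        in_channels: int,
        length: int,
        conv_filters: tuple[int, int] = (16, 32),
        kernel: int = 7,
        dense_units: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
    ):
        self.kernel = kernel
        self.lr = lr
        rng = np.random.default_rng(seed)
        f1, f2 = conv_filters

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        self.params = {
            "W1": he((in_channels * kernel, f1), in_channels * kernel),
            "b1": np.zeros(f1, np.float32),
            "W2": he((f1 * kernel, f2), f1 * kernel),
            "b2": np.zeros(f2, np.float32),
            "W3": he((f2, dense_units), f2),
            "b3": np.zeros(dense_units, np.float32),
            "W4": he((dense_units, 1), dense_units),
            "b4": np.zeros(1, np.float32),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------
    @staticmethod
    def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, k: int):
        # x: (N, L, C) -> patches (N, Lo, C*k) with index c*k + t
        win = sliding_window_view(x, k, axis=1)          # (N, Lo, C, k)
        patches = win.reshape(win.shape[0], win.shape[1], -1)
        y = patches @ W + b
        return y, patches

    @staticmethod
    def _conv_backward(dy, patches, W, x_shape, k):
        N, Lo, _ = dy.shape
        dW = patches.reshape(-1, patches.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        db = dy.sum(axis=(0, 1))
        dx = np.zeros(x_shape, np.float32)
        C = x_shape[2]
        Wr = W.reshape(C, k, -1)                          # (C, k, F)
        for t in range(k):
            dx[:, t:t + Lo, :] += dy @ Wr[:, t, :].T
        return dW.astype(np.float32), db.astype(np.float32), dx

    @staticmethod
    def _pool2(x):
        L2 = (x.shape[1] // 2) * 2
        x = x[:, :L2]
        return 0.5 * (x[:, 0::2] + x[:, 1::2])

    @staticmethod
    def _pool2_backward(dy, in_len):
        N, Lo, C = dy.shape
        dx = np.zeros((N, in_len, C), np.float32)
        dx[:, 0:2 * Lo:2] = 0.5 * dy
        dx[:, 1:2 * Lo:2] = 0.5 * dy
        return dx

    # ------------------------------------------------------------------
    def _forward(self, x: np.ndarray, cache: bool = False):
        p, k = self.params, self.kernel
        z1, patches1 = self._conv_forward(x, p["W1"], p["b1"], k)
        a1 = _relu(z1)
        p1 = self._pool2(a1)
        z2, patches2 = self._conv_forward(p1, p["W2"], p["b2"], k)
        a2 = _relu(z2)
        p2 = self._pool2(a2)
        g = p2.mean(axis=1)                               # GAP (N, F2)
        z3 = g @ p["W3"] + p["b3"]
        a3 = _relu(z3)
        z4 = a3 @ p["W4"] + p["b4"]
        out = 1.0 / (1.0 + np.exp(-z4[:, 0]))
        if not cache:
            return out
        return out, (x, patches1, z1, a1, p1, patches2, z2, a2, p2, g, z3, a3)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.ascontiguousarray(x, dtype=np.float32))

    # ------------------------------------------------------------------
    def _step(self, x: np.ndarray, t: np.ndarray) -> float:
        p, k = self.params, self.kernel
        out, cache = self._forward(x, cache=True)
        (xin, patches1, z1, a1, p1, patches2, z2, a2, p2, g, z3, a3) = cache
        N = x.shape[0]
        loss = float(np.mean((out - t) ** 2))

        dz4 = (2.0 / N) * (out - t) * out * (1.0 - out)   # (N,)
        dz4 = dz4[:, None].astype(np.float32)
        grads = {}
        grads["W4"] = a3.T @ dz4
        grads["b4"] = dz4.sum(axis=0)
        da3 = dz4 @ p["W4"].T
        dz3 = da3 * (z3 > 0)
        grads["W3"] = g.T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dg = dz3 @ p["W3"].T
        dp2 = np.repeat(dg[:, None, :], p2.shape[1], axis=1) / p2.shape[1]
        da2 = self._pool2_backward(dp2, a2.shape[1])
        dz2 = da2 * (z2 > 0)
        grads["W2"], grads["b2"], dp1 = self._conv_backward(
            dz2, patches2, p["W2"], p1.shape, k
        )
        da1 = self._pool2_backward(dp1, a1.shape[1])
        dz1 = da1 * (z1 > 0)
        grads["W1"], grads["b1"], _ = self._conv_backward(
            dz1, patches1, p["W1"], xin.shape, k
        )

        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for key, gr in grads.items():
            m = self._adam_m[key] = b1 * self._adam_m[key] + (1 - b1) * gr
            v = self._adam_v[key] = b2 * self._adam_v[key] + (1 - b2) * gr * gr
            mh = m / (1 - b1 ** self._adam_t)
            vh = v / (1 - b2 ** self._adam_t)
            self.params[key] -= (self.lr * mh / (np.sqrt(vh) + eps)).astype(np.float32)
        return loss

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 20,
        batch_size: int = 64,
        shuffle_seed: int = 0,
        verbose: bool = False,
    ) -> list[float]:
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        rng = np.random.default_rng(shuffle_seed)
        history = []
        for ep in range(epochs):
            order = rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), batch_size):
                idx = order[start:start + batch_size]
                losses.append(self._step(X[idx], y[idx]))
            history.append(float(np.mean(losses)))
            if verbose:
                print(f"epoch {ep + 1}: mse={history[-1]:.4f}")
        return history

    # -- (de)serialisation ---------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], np.float32)
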