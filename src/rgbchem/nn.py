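"""Minimal numpy neural-network kernels for the compact CNN regressors.

No deep-learning framework is assumed at run time, so the handful of
layers the S1CNN/S2CNN architectures need — 3x3 same-padding convolution,
ReLU, 2x2 max pooling, dense layers — plus the Adam optimizer are
implemented here directly on numpy arrays.  Everything operates on
``(batch, channels, height, width)`` float32/float64 tensors, is fully
deterministic given the seeded initializer, and supports exact
state capture/restore (for best-validation-weight checkpointing).

This is deliberately a small, single-threaded CPU implementation: the
models it serves have ~10^5 parameters and consume 32-48 pixel images,
where im2col-style convolution via nine shifted tensordot calls is fast
enough.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base: layers own ``params`` / ``grads`` dicts and cache activations."""

    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.params.values())


class Conv2d(Layer):
    """3x3 (or k x k) convolution, stride 1, 'same' zero padding.

    Implemented as a sum over the k*k kernel offsets of channel-mixing
    tensordots, which keeps both passes allocation-light at these sizes.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel)),
            "b": np.zeros(out_ch),
        }

    def forward(self, x, train=True):
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        if train:
            self._xp = xp
        b_, c, h, w = x.shape
        w_ = self.params["w"]
        out = np.empty((b_, self.out_ch, h, w))
        out[:] = self.params["b"][None, :, None, None]
        for di in range(k):
            for dj in range(k):
                # (B,C,H,W) x (O,C) -> (B,O,H,W)
                out += np.tensordot(
                    xp[:, :, di : di + h, dj : dj + w], w_[:, :, di, dj], axes=([1], [1])
                ).transpose(0, 3, 1, 2)
        return out

    def backward(self, dout):
        k = self.k
        xp = self._xp
        b_, _, h, w = dout.shape
        w_ = self.params["w"]
        dw = np.zeros_like(w_)
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                patch = xp[:, :, di : di + h, dj : dj + w]
                # dL/dw[o,c,di,dj] = sum_bhw dout[b,o,h,w] * patch[b,c,h,w]
                dw[:, :, di, dj] = np.tensordot(dout, patch, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, di : di + h, dj : dj + w] += np.tensordot(
                    dout, w_[:, :, di, dj], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        self.grads = {"w": dw, "b": dout.sum(axis=(0, 2, 3))}
        p = k // 2
        return dxp[:, :, p : p + xp.shape[2] - 2 * p, p : p + xp.shape[3] - 2 * p]


class ReLU(Layer):
    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    """max(x, alpha*x); the small negative slope prevents dead units, which
    matters for the narrow dense layers of the compact regression heads."""

    def __init__(self, alpha: float = 0.01):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.where(x > 0, x, self.alpha * x)

    def backward(self, dout):
        return dout * np.where(self._mask, 1.0, self.alpha)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train=True):
        b, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        win = x[:, :, : 2 * ho, : 2 * wo].reshape(b, c, ho, 2, wo, 2)
        win = win.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho, wo, 4)
        idx = win.argmax(axis=-1)
        if train:
            self._idx, self._shape = idx, x.shape
        return np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        b, c, h, w = self._shape
        ho, wo = h // 2, w // 2
        flat = np.zeros((b, c, ho, wo, 4))
        np.put_along_axis(flat, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((b, c, h, w))
        dx[:, :, : 2 * ho, : 2 * wo] = (
            flat.reshape(b, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, 2 * ho, 2 * wo)
        )
        return dx


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim)),
            "b": np.zeros(out_dim),
        }

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"w": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["w"].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def get_state(self) -> list[dict]:
        return [{k: v.copy() for k, v in layer.params.items()} for layer in self.layers]

    def set_state(self, state: list[dict]) -> None:
        for layer, params in zip(self.layers, state):
            for k, v in params.items():
                layer.params[k] = v.copy()


class Adam:
    """Adam with bias correction; beta1 plays the role of 'momentum'."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in model.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in model.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for li, layer in enumerate(self.model.layers):
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                m = self.m[li][k] = self.b1 * self.m[li][k] + (1 - self.b1) * g
                v = self.v[li][k] = self.b2 * self.v[li][k] + (1 - self.b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff * diff)), 2.0 * diff / diff.size
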