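"""Minimal NumPy neural-network toolkit.

Implements the layers needed by the shape autoencoder and the episodic
image backbones: 2-D convolution, transposed convolution, max pooling,
ReLU/Sigmoid, linear, global average pooling, plus SGD and Adam
optimizers.  Forward/backward passes are written against the im2col
(`sliding_window_view`) formulation and are exact: every layer is
verified against central finite differences in the test suite.

Arrays follow the (N, C, H, W) convention, float64 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2d", "ConvTranspose2d", "MaxPool2d", "ReLU", "Sigmoid",
    "Flatten", "GlobalAvgPool", "Linear", "Residual", "Sequential",
    "SGD", "Adam",
]


# ---------------------------------------------------------------- low-level conv

def _pad_pairs(pad):
    """Normalize pad spec to ((top, bottom), (left, right))."""
    if isinstance(pad, int):
        return (pad, pad), (pad, pad)
    return pad


def _conv2d_forward(x, W, stride, pad):
    """x (N,C,H,W), W (O,C,k,k) -> y (N,O,H',W') plus cache for backward.

    im2col + GEMM so the heavy lifting runs in BLAS.
    """
    (pt, pb), (pl, pr) = _pad_pairs(pad)
    O, C, k, _ = W.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    N, _, Ho, Wo = win.shape[:4]
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * k * k)
    y = (col @ W.reshape(O, -1).T).reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    return y, (col, xp.shape, x.shape, stride, pad, k, (N, Ho, Wo, C))


def _conv2d_backward(gy, W, cache):
    col, xp_shape, x_shape, stride, pad, k, (N, Ho, Wo, C) = cache
    (pt, pb), (pl, pr) = _pad_pairs(pad)
    O = W.shape[0]
    gym = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
    dW = (gym.T @ col).reshape(W.shape)
    dcol = (gym @ W.reshape(O, -1)).reshape(N, Ho, Wo, C, k, k)
    dxp = np.zeros(xp_shape, dtype=gy.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    H, Wd = x_shape[2], x_shape[3]
    dx = dxp[:, :, pt:pt + H, pl:pl + Wd]
    return dx, dW


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


# ---------------------------------------------------------------------- layers

class Layer:
    """Base layer: holds `params` and matching `grads` dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, in_ch, out_ch, k=3, stride=1, pad=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad = stride, pad
        self.params = {
            "W": _he_init(rng, (out_ch, in_ch, k, k), in_ch * k * k),
            "b": np.zeros(out_ch),
        }

    def forward(self, x, train=True):
        y, self._cache = _conv2d_forward(x, self.params["W"], self.stride, self.pad)
        return y + self.params["b"][None, :, None, None]

    def backward(self, gy):
        dx, dW = _conv2d_backward(gy, self.params["W"], self._cache)
        self.grads = {"W": dW, "b": gy.sum(axis=(0, 2, 3))}
        return dx


class ConvTranspose2d(Layer):
    """Stride-s transposed convolution (zero-dilation + stride-1 conv).

    With k=3, stride=2, pad=1, output_padding=1 the spatial size exactly
    doubles, mirroring a stride-2 Conv2d.
    """

    def __init__(self, in_ch, out_ch, k=3, stride=2, pad=1, output_padding=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad, self.opad = k, stride, pad, output_padding
        self.params = {
            "W": _he_init(rng, (in_ch, out_ch, k, k), in_ch * k * k),
            "b": np.zeros(out_ch),
        }

    def forward(self, x, train=True):
        N, C, H, Wd = x.shape
        s, k, p = self.stride, self.k, self.pad
        W = self.params["W"]
        out_h = (H - 1) * s - 2 * p + k + self.opad
        out_w = (Wd - 1) * s - 2 * p + k + self.opad
        # scatter per kernel tap: y[i + s*h - p, j + s*w - p] += x . W[:,:,i,j]
        yp = np.zeros((N, W.shape[1], (H - 1) * s + k, (Wd - 1) * s + k),
                      dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                t = np.tensordot(x, W[:, :, i, j], axes=([1], [0]))
                yp[:, :, i:i + s * H:s, j:j + s * Wd:s] += t.transpose(0, 3, 1, 2)
        self._x = x
        return yp[:, :, p:p + out_h, p:p + out_w] + self.params["b"][None, :, None, None]

    def backward(self, gy):
        x = self._x
        N, C, H, Wd = x.shape
        s, k, p = self.stride, self.k, self.pad
        W = self.params["W"]
        extra = (H - 1) * s + k - (gy.shape[2] + p)  # right/bottom slack
        gyp = np.pad(gy, ((0, 0), (0, 0), (p, extra), (p, extra)))
        dx = np.zeros_like(x)
        dW = np.zeros_like(W)
        for i in range(k):
            for j in range(k):
                g = gyp[:, :, i:i + s * H:s, j:j + s * Wd:s]
                dx += np.tensordot(g, W[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
                dW[:, :, i, j] = np.tensordot(x, g, axes=([0, 2, 3], [0, 2, 3]))
        self.grads = {"W": dW, "b": gy.sum(axis=(0, 2, 3))}
        return dx


class MaxPool2d(Layer):
    """2x2 max pooling; requires even spatial dims. First-argmax routing."""

    def __init__(self):
        super().__init__()

    def forward(self, x, train=True):
        N, C, H, W = x.shape
        xf = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xf = xf.reshape(N, C, H // 2, W // 2, 4)
        self._idx = xf.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xf, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        N, C, H, W = self._shape
        gf = np.zeros((N, C, H // 2, W // 2, 4), dtype=gy.dtype)
        np.put_along_axis(gf, self._idx[..., None], gy[..., None], axis=-1)
        gf = gf.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gf.reshape(N, C, H, W)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._m = x > 0
        return x * self._m

    def backward(self, gy):
        return gy * self._m


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class GlobalAvgPool(Layer):
    """Spatial mean per channel -> (N, C)."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        N, C, H, W = self._shape
        return np.broadcast_to(gy[:, :, None, None], self._shape) / (H * W)


class Linear(Layer):
    def __init__(self, in_f, out_f, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {"W": _he_init(rng, (in_f, out_f), in_f), "b": np.zeros(out_f)}

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy):
        self.grads = {"W": self._x.T @ gy, "b": gy.sum(axis=0)}
        return gy @ self.params["W"].T


class Residual(Layer):
    """y = relu(body(x) + shortcut(x)); shortcut=None means identity."""

    def __init__(self, body, shortcut=None):
        super().__init__()
        self.body = body
        self.shortcut = shortcut

    def forward(self, x, train=True):
        b = self.body.forward(x, train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        self._m = (b + s) > 0
        return (b + s) * self._m

    def backward(self, gy):
        g = gy * self._m
        db = self.body.backward(g)
        ds = g if self.shortcut is None else self.shortcut.backward(g)
        return db + ds

    def layers(self):
        out = self.body.layers()
        if self.shortcut is not None:
            out += self.shortcut.layers()
        return out


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self._layers = list(layers)

    def forward(self, x, train=True):
        for layer in self._layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy):
        for layer in reversed(self._layers):
            gy = layer.backward(gy)
        return gy

    def layers(self):
        out = []
        for layer in self._layers:
            if isinstance(layer, (Sequential, Residual)):
                out += layer.layers()
            else:
                out.append(layer)
        return out

    def astype(self, dtype):
        """Cast all parameters in place (e.g. float32 for faster training)."""
        for layer in self.layers():
            layer.params = {k: v.astype(dtype) for k, v in layer.params.items()}
        return self

    # -- parameter (de)serialization: flat dict keyed by layer index ----------
    def state_dict(self):
        state = {}
        for i, layer in enumerate(self.layers()):
            for k, v in layer.params.items():
                state[f"{i}.{k}"] = v.copy()
        return state

    def load_state_dict(self, state):
        for i, layer in enumerate(self.layers()):
            for k in layer.params:
                layer.params[k] = state[f"{i}.{k}"].copy()


# ------------------------------------------------------------------ optimizers

class SGD:
    def __init__(self, model: Sequential, lr=1e-3, weight_decay=0.0, momentum=0.9):
        self.model, self.lr, self.wd, self.mom = model, lr, weight_decay, momentum
        self._vel = [{k: np.zeros_like(v) for k, v in l.params.items()}
                     for l in model.layers()]

    def step(self):
        for layer, vel in zip(self.model.layers(), self._vel):
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                g = g + self.wd * p
                vel[k] = self.mom * vel[k] + g
                p -= self.lr * vel[k]

    def zero_grad(self):
        for layer in self.model.layers():
            layer.grads = {}


class Adam:
    def __init__(self, model: Sequential, lr=1e-3, weight_decay=0.0,
                 betas=(0.9, 0.999), eps=1e-8):
        self.model, self.lr, self.wd = model, lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                   for l in model.layers()]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                   for l in model.layers()]

    def step(self):
        self.t += 1
        for layer, m, v in zip(self.model.layers(), self._m, self._v):
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                g = g + self.wd * p
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                mhat = m[k] / (1 - self.b1 ** self.t)
                vhat = v[k] / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for layer in self.model.layers():
            layer.grads = {}
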