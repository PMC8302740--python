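"""A compact numpy neural-network engine (2D conv nets with backprop).

Implements exactly the layers the intensity-mapping networks need —
Conv2d, ConvTranspose2d, BatchNorm2d, ReLU/LeakyReLU/Tanh, MaxPool2d,
residual blocks — with explicit forward caches and analytic backward
passes, plus an Adam optimizer. Convolutions are im2col/col2im based so
the heavy lifting is BLAS matmuls. All computation is float64 and fully
deterministic given the seeded initializer.

Layer API: ``forward(x, train) -> (y, cache)`` and
``backward(dy, cache) -> dx`` with parameter gradients accumulated into
``layer.grads``; a cache per call makes repeated forwards (as in cycle
reconstruction paths) safe.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "ConvTranspose2d", "BatchNorm2d", "ReLU", "LeakyReLU",
    "Tanh", "MaxPool2d", "Sequential", "ResidualBlock", "Adam",
]


def _im2col(xp: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    """(N,C,Hp,Wp) padded input -> (N, Ho*Wo, C*k*k) patch matrix."""
    n, c, hp, wp = xp.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N,C,Ho,Wo,k,k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, padded_shape, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """Scatter-add patch gradients back onto the padded input grid."""
    n, c, hp, wp = padded_shape
    dx = np.zeros((n, c, hp, wp))
    d6 = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d6[..., i, j]
    return dx


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True):
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache):
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def layers(self):
        return [self]


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None, init_std: float = 0.02):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["w"] = rng.normal(0.0, init_std, size=(out_ch, in_ch, kernel, kernel))
        self.params["b"] = np.zeros(out_ch)
        self.zero_grad()

    def forward(self, x, train=True):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols, ho, wo = _im2col(xp, self.kernel, self.stride)
        wf = self.params["w"].reshape(self.out_ch, -1)
        y = cols @ wf.T + self.params["b"]
        y = y.reshape(x.shape[0], ho, wo, self.out_ch).transpose(0, 3, 1, 2)
        return y, (cols, xp.shape, ho, wo)

    def backward(self, dy, cache):
        cols, padded_shape, ho, wo = cache
        n = dy.shape[0]
        dyf = dy.transpose(0, 2, 3, 1).reshape(n, ho * wo, self.out_ch)
        wf = self.params["w"].reshape(self.out_ch, -1)
        self.grads["w"] += np.einsum("nlo,nlk->ok", dyf, cols).reshape(self.params["w"].shape)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        dcols = dyf @ wf
        dxp = _col2im(dcols, padded_shape, self.kernel, self.stride, ho, wo)
        p = self.pad
        return dxp[:, :, p : dxp.shape[2] - p, p : dxp.shape[3] - p] if p else dxp


class ConvTranspose2d(Layer):
    """Stride-s transposed convolution (the adjoint of Conv2d)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 2,
                 pad: int = 1, output_padding: int = 1,
                 rng: np.random.Generator | None = None, init_std: float = 0.02):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.kernel, self.stride, self.pad, self.opad = kernel, stride, pad, output_padding
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["w"] = rng.normal(0.0, init_std, size=(in_ch, out_ch, kernel, kernel))
        self.params["b"] = np.zeros(out_ch)
        self.zero_grad()

    def _padded_out_hw(self, h, w):
        k, s, op = self.kernel, self.stride, self.opad
        return (h - 1) * s + k + op, (w - 1) * s + k + op

    def forward(self, x, train=True):
        n, _, h, w = x.shape
        hp, wp = self._padded_out_hw(h, w)
        xf = x.transpose(0, 2, 3, 1).reshape(n, h * w, self.in_ch)
        wf = self.params["w"].reshape(self.in_ch, -1)  # (in, out*k*k)
        dcols = xf @ wf  # (n, h*w, out*k*k)
        yp = _col2im(dcols, (n, self.out_ch, hp, wp), self.kernel, self.stride, h, w)
        p = self.pad
        y = yp[:, :, p : hp - p, p : wp - p] if p else yp
        y = y + self.params["b"][None, :, None, None]
        return y, (x, (n, h, w))

    def backward(self, dy, cache):
        x, (n, h, w) = cache
        hp, wp = self._padded_out_hw(h, w)
        p = self.pad
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, hp - dy.shape[2] - p), (p, wp - dy.shape[3] - p))) if (
            p or self.opad
        ) else dy
        cols, ho, wo = _im2col(dyp, self.kernel, self.stride)
        assert (ho, wo) == (h, w)
        wf = self.params["w"].reshape(self.in_ch, -1)
        xf = x.transpose(0, 2, 3, 1).reshape(n, h * w, self.in_ch)
        self.grads["w"] += np.einsum("nli,nlk->ik", xf, cols).reshape(self.params["w"].shape)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        dxf = cols @ wf.T  # (n, h*w, in)
        return dxf.reshape(n, h, w, self.in_ch).transpose(0, 3, 1, 2)


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.params["gamma"] = np.ones(ch)
        self.params["beta"] = np.zeros(ch)
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.zero_grad()

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]
        return y, (xhat, inv_std, train, x.shape)

    def backward(self, dy, cache):
        xhat, inv_std, train, shape = cache
        g = self.params["gamma"][None, :, None, None]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        if not train:
            return dy * g * inv_std[None, :, None, None]
        n = shape[0] * shape[2] * shape[3]
        dxhat = dy * g
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) - xhat * (
            (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        del n
        return term * inv_std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=True):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, cache):
        return dy * cache


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, dy, cache):
        return np.where(cache, dy, self.slope * dy)


class Tanh(Layer):
    def forward(self, x, train=True):
        y = np.tanh(x)
        return y, y

    def backward(self, dy, cache):
        return dy * (1.0 - cache**2)


class MaxPool2d(Layer):
    """2x2 max pooling (even spatial dims required)."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d(2) needs even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        return y, (idx, (n, c, h, w))

    def backward(self, dy, cache):
        idx, (n, c, h, w) = cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.children = list(layers)

    def forward(self, x, train=True):
        caches = []
        for layer in self.children:
            x, c = layer.forward(x, train)
            caches.append(c)
        return x, caches

    def backward(self, dy, caches):
        for layer, c in zip(reversed(self.children), reversed(caches)):
            dy = layer.backward(dy, c)
        return dy

    def zero_grad(self):
        for layer in self.children:
            layer.zero_grad()

    def layers(self):
        out = []
        for layer in self.children:
            out.extend(layer.layers())
        return out


class ResidualBlock(Layer):
    """conv-BN-ReLU-conv-BN with an identity skip (channel-preserving)."""

    def __init__(self, ch: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.body = Sequential(
            Conv2d(ch, ch, 3, pad=1, rng=rng),
            BatchNorm2d(ch),
            ReLU(),
            Conv2d(ch, ch, 3, pad=1, rng=rng),
            BatchNorm2d(ch),
        )

    def forward(self, x, train=True):
        y, cache = self.body.forward(x, train)
        return x + y, cache

    def backward(self, dy, cache):
        return dy + self.body.backward(dy, cache)

    def zero_grad(self):
        self.body.zero_grad()

    def layers(self):
        return self.body.layers()


class Adam:
    """Adam over the parameters of a set of layers."""

    def __init__(self, layers, lr: float = 2e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layer_list = []
        for top in layers:
            self.layer_list.extend(top.layers())
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in self.layer_list]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in self.layer_list]

    def zero_grad(self):
        for lay in self.layer_list:
            lay.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for lay, m, v in zip(self.layer_list, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)


def get_state(layers) -> list[dict[str, np.ndarray]]:
    """Flat snapshot of all parameters and batch-norm running stats."""
    out = []
    for top in layers:
        for lay in top.layers():
            d = {k: v.copy() for k, v in lay.params.items()}
            if isinstance(lay, BatchNorm2d):
                d["running_mean"] = lay.running_mean.copy()
                d["running_var"] = lay.running_var.copy()
            out.append(d)
    return out


def set_state(layers, state) -> None:
    i = 0
    for top in layers:
        for lay in top.layers():
            d = state[i]
            for k in lay.params:
                lay.params[k] = d[k].copy()
            if isinstance(lay, BatchNorm2d):
                lay.running_mean = d["running_mean"].copy()
                lay.running_var = d["running_var"].copy()
            i += 1
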