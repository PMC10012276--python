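"""Minimal NumPy convolutional-network kernel with manual backpropagation.

Implements exactly what the dose predictor needs: strided/dilated 2D
convolution (im2col), fractionally-strided deconvolution, batch
normalization, ReLU, max pooling, residual bottleneck blocks and Adam.
Every layer exposes ``forward(x, train)`` and ``backward(dy)``; gradients
accumulate into ``Param.grad`` and are checked against central finite
differences in the test suite.

Arrays are (N, C, H, W) float32 by default; layers are dtype-agnostic so
gradient checks can run in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Sequential",
    "Bottleneck",
    "Adam",
    "mse_loss",
    "mae_loss",
]


class Param:
    """A learnable array plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    """Base layer: collects Params recursively from attributes and lists."""

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _out_size(n: int, k: int, stride: int, pad: int, dilation: int) -> int:
    return (n + 2 * pad - dilation * (k - 1) - 1) // stride + 1


def im2col(x, kh, kw, stride, pad, dilation, pad_value=0.0):
    """(N, C, H, W) -> (N, C, kh, kw, Ho, Wo) window view copy."""
    n, c, h, w = x.shape
    ho = _out_size(h, kh, stride, pad, dilation)
    wo = _out_size(w, kw, stride, pad, dilation)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=pad_value)
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        i0 = i * dilation
        for j in range(kw):
            j0 = j * dilation
            cols[:, :, i, j] = xp[:, :, i0 : i0 + stride * (ho - 1) + 1 : stride,
                                  j0 : j0 + stride * (wo - 1) + 1 : stride]
    return cols


def col2im(cols, x_shape, kh, kw, stride, pad, dilation):
    """Adjoint of ``im2col``: scatter-add windows back onto the image."""
    n, c, h, w = x_shape
    ho, wo = cols.shape[4:]
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        i0 = i * dilation
        for j in range(kw):
            j0 = j * dilation
            xp[:, :, i0 : i0 + stride * (ho - 1) + 1 : stride,
               j0 : j0 + stride * (wo - 1) + 1 : stride] += cols[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w]


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=0, dilation=1, bias=True, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.pad, self.dilation = stride, pad, dilation
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.weight = Param(rng.normal(0.0, std, size=(cout, fan_in)).astype(np.float32))
        self.bias = Param(np.zeros(cout, dtype=np.float32)) if bias else None
        self._cache = None

    def forward(self, x, train=True):
        n = x.shape[0]
        cols6 = im2col(x, self.k, self.k, self.stride, self.pad, self.dilation)
        ho, wo = cols6.shape[4:]
        cols = cols6.reshape(n, self.cin * self.k * self.k, ho * wo)
        y = np.matmul(self.weight.value, cols)
        if self.bias is not None:
            y = y + self.bias.value[:, None]
        self._cache = (cols, x.shape, ho, wo)
        return y.reshape(n, self.cout, ho, wo)

    def backward(self, dy):
        cols, x_shape, ho, wo = self._cache
        n = dy.shape[0]
        g = dy.reshape(n, self.cout, ho * wo)
        self.weight.grad += np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2))
        dcols = np.matmul(self.weight.value.T, g)
        dcols6 = dcols.reshape(n, self.cin, self.k, self.k, ho, wo)
        return col2im(dcols6, x_shape, self.k, self.k, self.stride, self.pad, self.dilation)


class ConvTranspose2x2(Module):
    """Fractionally-strided deconvolution with kernel 2, stride 2 (x2 upsampling)."""

    def __init__(self, cin, cout, bias=True, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / cin)
        self.weight = Param(rng.normal(0.0, std, size=(cin, cout, 2, 2)).astype(np.float32))
        self.bias = Param(np.zeros(cout, dtype=np.float32)) if bias else None
        self._cache = None

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        t = np.einsum("nchw,cokl->nohkwl", x, self.weight.value)
        y = t.reshape(n, self.cout, 2 * h, 2 * w)
        if self.bias is not None:
            y = y + self.bias.value[None, :, None, None]
        self._cache = x
        return y

    def backward(self, dy):
        x = self._cache
        n, c, h, w = x.shape
        d6 = dy.reshape(n, self.cout, h, 2, w, 2)
        self.weight.grad += np.einsum("nchw,nohkwl->cokl", x, d6)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        return np.einsum("nohkwl,cokl->nchw", d6, self.weight.value)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * istd[None, :, None, None]
        self._cache = (xhat, istd.astype(x.dtype), train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, istd, train, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        if not train:
            return dxhat * istd[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (istd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Module):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Module):
    def __init__(self, k=3, stride=2, pad=1):
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        cols6 = im2col(x, self.k, self.k, self.stride, self.pad, 1, pad_value=-np.inf)
        ho, wo = cols6.shape[4:]
        cols = cols6.reshape(n, c, self.k * self.k, ho * wo)
        idx = cols.argmax(axis=2)
        y = np.take_along_axis(cols, idx[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (idx, x.shape, ho, wo)
        return y.reshape(n, c, ho, wo)

    def backward(self, dy):
        idx, x_shape, ho, wo = self._cache
        n, c = x_shape[:2]
        dcols = np.zeros((n, c, self.k * self.k, ho * wo), dtype=dy.dtype)
        np.put_along_axis(dcols, idx[:, :, None, :], dy.reshape(n, c, 1, ho * wo), axis=2)
        dcols6 = dcols.reshape(n, c, self.k, self.k, ho, wo)
        return col2im(dcols6, x_shape, self.k, self.k, self.stride, self.pad, 1)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Bottleneck(Module):
    """Residual 1x1 -> 3x3 -> 1x1 block with identity or projection skip."""

    def __init__(self, cin, mid, cout, stride=1, dilation=1, rng=None):
        self.conv1 = Conv2d(cin, mid, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(mid)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(mid, mid, 3, stride=stride, pad=dilation, dilation=dilation, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(mid)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(mid, cout, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.downsample = Sequential(
                Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng), BatchNorm2d(cout)
            )
        else:
            self.downsample = None
        self._mask = None

    def forward(self, x, train=True):
        out = self.conv1.forward(x, train)
        out = self.relu1.forward(self.bn1.forward(out, train), train)
        out = self.conv2.forward(out, train)
        out = self.relu2.forward(self.bn2.forward(out, train), train)
        out = self.bn3.forward(self.conv3.forward(out, train), train)
        skip = self.downsample.forward(x, train) if self.downsample is not None else x
        s = out + skip
        self._mask = s > 0
        return s * self._mask

    def backward(self, dy):
        ds = dy * self._mask
        d = self.conv3.backward(self.bn3.backward(ds))
        d = self.bn2.backward(self.relu2.backward(d))
        d = self.conv2.backward(d)
        d = self.bn1.backward(self.relu1.backward(d))
        dx = self.conv1.backward(d)
        if self.downsample is not None:
            dx = dx + self.downsample.backward(ds)
        else:
            dx = dx + ds
        return dx


class Adam:
    def __init__(self, params: list[Param], lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)).astype(p.value.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0


def mse_loss(y: np.ndarray, t: np.ndarray):
    """Mean squared error and its gradient w.r.t. ``y``."""
    diff = y - t
    loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff


def mae_loss(y: np.ndarray, t: np.ndarray):
    """Mean absolute error and its (sub)gradient w.r.t. ``y``."""
    diff = y - t
    loss = float(np.mean(np.abs(diff)))
    return loss, np.sign(diff) / diff.size
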