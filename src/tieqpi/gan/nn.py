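"""Minimal numpy neural-network layers with hand-written backprop.

Data layout is NCHW float32.  Each layer exposes ``forward(x, train)``
and ``backward(grad)`` (returning the gradient with respect to its
input and caching parameter gradients), plus ``params()`` yielding
(parameter, gradient, state) triples consumed by :class:`Adam`.

Only what the cGAN needs is implemented: strided convolution and
transposed convolution (the exact adjoint pair), batch normalization,
leaky ReLU / ReLU / tanh, and inverted dropout.  Convolutions use an
im2col formulation; the transposed convolution reuses the col2im
scatter, so conv/conv-transpose gradients are exact adjoints by
construction.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F = np.float32


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, H, W) -> columns (N, C*k*k, Ho*Wo)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), (ho, wo)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    """Adjoint of :func:`_im2col`: scatter-add columns back to an image."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += cols[
                :, :, ki, kj
            ]
    return xp[:, :, pad : pad + h, pad : pad + w]


class Conv2d:
    """k x k convolution, stride s, symmetric zero padding."""

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None, bias=True):
        rng = rng or np.random.default_rng()
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self.W = rng.normal(0.0, 0.02, (cout, cin * k * k)).astype(F)
        self.b = np.zeros(cout, dtype=F) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._state: dict = {}

    def out_shape(self, h, w):
        return (
            (h + 2 * self.pad - self.k) // self.stride + 1,
            (w + 2 * self.pad - self.k) // self.stride + 1,
        )

    def forward(self, x, train=True):
        self.x_shape = x.shape
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        self.cols = cols if train else None
        y = np.einsum("oc,ncl->nol", self.W, cols, optimize=True)
        if self.b is not None:
            y += self.b[None, :, None]
        return y.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, gy):
        n, _, ho, wo = gy.shape
        g = gy.reshape(n, self.cout, ho * wo)
        self.dW = np.einsum("nol,ncl->oc", g, self.cols, optimize=True)
        if self.b is not None:
            self.db = g.sum(axis=(0, 2))
        dcols = np.einsum("oc,nol->ncl", self.W, g, optimize=True)
        return _col2im(dcols, self.x_shape, self.k, self.stride, self.pad)

    def params(self):
        yield self.W, lambda: self.dW, self._state.setdefault("W", {})
        if self.b is not None:
            yield self.b, lambda: self.db, self._state.setdefault("b", {})


class ConvTranspose2d:
    """Transposed (fractionally strided) convolution, the adjoint of Conv2d."""

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None):
        rng = rng or np.random.default_rng()
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        # stored in the "conv that this transposes" orientation
        self.W = rng.normal(0.0, 0.02, (cin, cout * k * k)).astype(F)
        self.b = np.zeros(cout, dtype=F)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._state: dict = {}

    def out_shape(self, h, w):
        return (
            self.stride * (h - 1) + self.k - 2 * self.pad,
            self.stride * (w - 1) + self.k - 2 * self.pad,
        )

    def forward(self, x, train=True):
        n, cin, h, w = x.shape
        ho, wo = self.out_shape(h, w)
        self.x = x if train else None
        self._hw = (h, w)
        xr = x.reshape(n, cin, h * w)
        cols = np.einsum("cm,ncl->nml", self.W, xr, optimize=True)
        y = _col2im(cols, (n, self.cout, ho, wo), self.k, self.stride, self.pad)
        return y + self.b[None, :, None, None]

    def backward(self, gy):
        n = gy.shape[0]
        h, w = self._hw
        cols, _ = _im2col(gy, self.k, self.stride, self.pad)
        xr = self.x.reshape(n, self.cin, h * w)
        self.dW = np.einsum("ncl,nml->cm", xr, cols, optimize=True)
        self.db = gy.sum(axis=(0, 2, 3))
        gx = np.einsum("cm,nml->ncl", self.W, cols, optimize=True)
        return gx.reshape(n, self.cin, h, w)

    def params(self):
        yield self.W, lambda: self.dW, self._state.setdefault("W", {})
        yield self.b, lambda: self.db, self._state.setdefault("b", {})


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c, momentum=0.1, eps=1e-5, rng=None):
        rng = rng or np.random.default_rng()
        self.gamma = rng.normal(1.0, 0.02, c).astype(F)
        self.beta = np.zeros(c, dtype=F)
        self.run_mean = np.zeros(c, dtype=F)
        self.run_var = np.ones(c, dtype=F)
        self.momentum, self.eps = momentum, eps
        self.update_running = True
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._state: dict = {}

    def forward(self, x, train=True):
        ax = (0, 2, 3)
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            if self.update_running:
                self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
                self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        std = np.sqrt(var + self.eps)
        self.xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self.std = std
        self.m = x.shape[0] * x.shape[2] * x.shape[3]
        return self.gamma[None, :, None, None] * self.xhat + self.beta[None, :, None, None]

    def backward(self, gy):
        ax = (0, 2, 3)
        self.dgamma = (gy * self.xhat).sum(axis=ax)
        self.dbeta = gy.sum(axis=ax)
        gxhat = gy * self.gamma[None, :, None, None]
        # standard batch-norm backward (train-mode statistics)
        t = gxhat - gxhat.mean(axis=ax, keepdims=True) - self.xhat * (
            (gxhat * self.xhat).mean(axis=ax, keepdims=True)
        )
        return t / self.std[None, :, None, None]

    def params(self):
        yield self.gamma, lambda: self.dgamma, self._state.setdefault("g", {})
        yield self.beta, lambda: self.dbeta, self._state.setdefault("b", {})


class LeakyReLU:
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x, train=True):
        self.mask = x >= 0
        return np.where(self.mask, x, self.slope * x)

    def backward(self, gy):
        return np.where(self.mask, gy, self.slope * gy)

    def params(self):
        return ()


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh:
    def forward(self, x, train=True):
        self.y = np.tanh(x)
        return self.y

    def backward(self, gy):
        return gy * (1.0 - self.y**2)

    def params(self):
        return ()


class Dropout:
    """Inverted dropout; active in train mode (and optionally at inference
    to realize the cGAN noise input)."""

    def __init__(self, rate, rng):
        self.rate, self.rng = rate, rng
        self.enabled = True

    def forward(self, x, train=True):
        if not train or not self.enabled or self.rate <= 0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (self.rng.random(x.shape) < keep).astype(F) / F(keep)
        return x * self.mask

    def backward(self, gy):
        return gy if self.mask is None else gy * self.mask

    def params(self):
        return ()


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy

    def params(self):
        for l in self.layers:
            yield from l.params()


class Adam:
    """Adam with pix2pix-convention betas (0.5, 0.999)."""

    def __init__(self, lr=1e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps

    def step(self, params):
        for p, grad_fn, st in params:
            g = grad_fn().astype(F)
            if "m" not in st:
                st["m"] = np.zeros_like(p)
                st["v"] = np.zeros_like(p)
                st["t"] = 0
            st["t"] += 1
            st["m"] = self.b1 * st["m"] + (1 - self.b1) * g
            st["v"] = self.b2 * st["v"] + (1 - self.b2) * g * g
            mhat = st["m"] / (1 - self.b1 ** st["t"])
            vhat = st["v"] / (1 - self.b2 ** st["t"])
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def bce_with_logits(logits, target):
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    # stable: log(1+exp(-|z|)) formulation
    loss = np.mean(np.maximum(logits, 0) - logits * target + np.log1p(np.exp(-np.abs(logits))))
    grad = (sigmoid(logits) - target) / logits.size
    return float(loss), grad.astype(F)
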