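"""Minimal CPU neural-network core (NumPy, manual backprop).

Provides exactly the layers the stain-conversion networks need: 2-D
convolution (im2col), instance normalisation, LeakyReLU/ReLU/Tanh,
nearest-neighbour 2x upsampling, and the Adam optimiser.

Layers are *functional*: ``forward`` returns ``(output, cache)`` and
``backward(cache, grad_out)`` returns the input gradient while
accumulating parameter gradients. Because caches live outside the layer,
the same module may appear several times in one computation graph (as the
generators do in a cycle-consistency pass). Tensors are (N, C, H, W)
float64; all randomness comes from an explicit ``numpy.random.Generator``
so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "InstanceNorm2d", "LeakyReLU", "ReLU", "Tanh",
           "Upsample2x", "Sequential", "Adam", "set_default_dtype"]

# float32 is the working precision (ample for GAN training and twice as
# fast); switch to float64 for e.g. finite-difference gradient checks.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    """Set the dtype used by parameters created afterwards."""
    global DTYPE
    DTYPE = np.dtype(dtype).type


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, cache, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded strided convolution via im2col."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, rng=None, name="conv"):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride = kernel, stride
        rng = rng or np.random.default_rng(0)
        # He-scaled init: at small widths the skip connections then carry
        # input structure from the first forward pass onwards, which helps
        # the adversarial signal pick the correct output polarity
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(out_ch), f"{name}.b")
        # 'same' padding for stride 1; for stride s the output is H/s
        self.pad = (kernel - 1) // 2

    def params(self):
        return [self.w, self.b]

    def _im2col(self, x):
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        if p:
            xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=x.dtype)
            xp[:, :, p : p + h, p : p + w] = x
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, ho, wo, k, k)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
        return cols, (ho, wo, xp.shape)

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=self.w.value.dtype)
        n = x.shape[0]
        cols, (ho, wo, xp_shape) = self._im2col(x)
        wmat = self.w.value.reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.b.value  # (n, L, out_ch)
        y = out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(y), (x.shape, cols, xp_shape, ho, wo)

    def backward(self, cache, dy):
        x_shape, cols, xp_shape, ho, wo = cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        dy = np.ascontiguousarray(dy, dtype=self.w.value.dtype)
        dout = dy.transpose(0, 2, 3, 1).reshape(n, ho * wo, self.out_ch)
        wmat = self.w.value.reshape(self.out_ch, -1)
        self.b.grad += dout.sum(axis=(0, 1))
        # (out_ch, c*k*k) accumulated over batch, as one BLAS call
        dwmat = dout.reshape(-1, self.out_ch).T @ cols.reshape(-1, cols.shape[2])
        self.w.grad += dwmat.reshape(self.w.value.shape)
        dcols = dout @ wmat  # (n, L, c*k*k)
        dcols = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros(xp_shape)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[..., i, j]
        return dxp[:, :, p : p + h, p : p + w]


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalisation with learned affine."""

    def __init__(self, channels, eps=1e-5, name="in"):
        self.eps = eps
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        return y, (xhat, inv)

    def backward(self, cache, dy):
        xhat, inv = cache
        m = xhat.shape[2] * xhat.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        # standard normalisation backward over the spatial axes
        dx = (
            dxhat
            - dxhat.mean(axis=(2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        ) * inv
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x):
        mask = x >= 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, cache, dy):
        return np.where(cache, dy, self.slope * dy)


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, cache, dy):
        return dy * cache


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, cache, dy):
        return dy * (1.0 - cache**2)


class Upsample2x(Layer):
    """Nearest-neighbour doubling of the spatial dimensions."""

    def forward(self, x):
        y = x.repeat(2, axis=2).repeat(2, axis=3)
        return y, x.shape

    def backward(self, cache, dy):
        n, c, h, w = cache
        return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        caches = []
        for l in self.layers:
            x, c = l.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, caches, dy):
        for l, c in zip(reversed(self.layers), reversed(caches)):
            dy = l.backward(c, dy)
        return dy


class Adam:
    """Adam optimiser over an explicit parameter list."""

    def __init__(self, params: list[Param], lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
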