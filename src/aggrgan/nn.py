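"""Layers and the Adam optimizer used by the GAN suite and style extractor.

Thin object wrappers over :mod:`aggrgan.autograd`.  Layers are deliberately
simple: parameters are float64 Tensors, initialization is fully determined by
the numpy Generator handed to the constructor, and stochastic layers
(dropout) draw from the Generator passed at call time so training runs are
bit-reproducible per seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    def parameters(self) -> list[Tensor]:
        return []

    def __call__(self, x, rng=None, train: bool = True):
        raise NotImplementedError

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        s = scale if scale is not None else np.sqrt(2.0 / n_in)
        self.w = Tensor(rng.standard_normal((n_in, n_out)) * s, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def parameters(self):
        return [self.w, self.b]

    def __call__(self, x, rng=None, train=True):
        return ag.matmul(x, self.w) + self.b


class Conv2d(Module):
    """Strided cross-correlation; DCGAN-style N(0, 0.02) weight init."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad=0, init_sd: float = 0.02):
        self.w = Tensor(rng.standard_normal((c_out, c_in, k, k)) * init_sd,
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad = stride, pad

    def parameters(self):
        return [self.w, self.b]

    def __call__(self, x, rng=None, train=True):
        return ag.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 2, pad: int = 1, init_sd: float = 0.02):
        self.w = Tensor(rng.standard_normal((c_in, c_out, k, k)) * init_sd,
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad = stride, pad

    def parameters(self):
        return [self.w, self.b]

    def __call__(self, x, rng=None, train=True):
        return ag.conv_transpose2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class BatchNorm(Module):
    """Batch normalization over the batch (and spatial axes for NCHW input).

    Always uses the current batch statistics; composed from differentiable
    primitives so its backward comes for free.
    """

    def __init__(self, n_channels: int, ndim: int = 4, eps: float = 1e-5):
        shape = (1, n_channels) + (1,) * (ndim - 2)
        self.gamma = Tensor(np.ones(shape), requires_grad=True)
        self.beta = Tensor(np.zeros(shape), requires_grad=True)
        self.axes = (0,) + tuple(range(2, ndim))
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def __call__(self, x, rng=None, train=True):
        mu = ag.tmean(x, axis=self.axes, keepdims=True)
        cent = x - mu
        var = ag.tmean(cent * cent, axis=self.axes, keepdims=True)
        xhat = cent * ag.powt(var + self.eps, -0.5)
        return xhat * self.gamma + self.beta


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def __call__(self, x, rng=None, train=True):
        return ag.leaky_relu(x, self.slope)


class Tanh(Module):
    def __call__(self, x, rng=None, train=True):
        return ag.tanh(x)


class Sigmoid(Module):
    def __call__(self, x, rng=None, train=True):
        return ag.sigmoid(x)


class Dropout(Module):
    """Inverted dropout; identity when not training or when no rng is given."""

    def __init__(self, p: float):
        self.p = p

    def __call__(self, x, rng=None, train=True):
        if not train or rng is None or self.p <= 0:
            return x
        keep = 1.0 - self.p
        mask = (rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)


class Reshape(Module):
    def __init__(self, shape):
        self.shape = tuple(shape)

    def __call__(self, x, rng=None, train=True):
        return ag.reshape(x, (x.data.shape[0],) + self.shape)


class Flatten(Module):
    def __call__(self, x, rng=None, train=True):
        return ag.reshape(x, (x.data.shape[0], -1))


class Upsample(Module):
    def __init__(self, factor: int = 2):
        self.factor = factor

    def __call__(self, x, rng=None, train=True):
        return ag.upsample_nearest(x, self.factor)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def __call__(self, x, rng=None, train=True):
        for layer in self.layers:
            x = layer(x, rng=rng, train=train)
        return x


class Adam:
    """Adam with the DCGAN convention beta1 = 0.5."""

    def __init__(self, params: list[Tensor], lr: float,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
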