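"""Minimal feed-forward neural-network kit on numpy.

Implements exactly the layer types the adversarial variant-interpretation
networks need (dense, 1-d convolution, batch normalization, leaky rectifier,
tanh, dropout) with hand-derived reverse-mode gradients and an Adam
optimizer.  Every layer caches what its backward pass needs during
``forward``; a full forward must therefore precede each backward on the
same module.

All randomness (initialization, dropout masks) flows through
``numpy.random.Generator`` objects supplied by the caller, so training runs
are bit-reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "LeakyReLU",
    "Tanh",
    "Dropout",
    "Flatten",
    "Sequential",
    "Adam",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value)
        if self.value.dtype not in (np.float32, np.float64):
            self.value = self.value.astype(np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: forward caches, backward consumes the cache."""

    def forward(self, x: np.ndarray, train: bool = True,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float64) -> None:
        # He-style init suits the leaky-rectifier nets used here
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale,
                                           (in_features, out_features)).astype(dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))
        self._x: np.ndarray | None = None

    def forward(self, x, train=True, rng=None):
        x = np.asarray(x, dtype=self.weight.value.dtype)
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad_out):
        self.weight.grad += self._x.T @ grad_out
        self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.value.T

    def parameters(self):
        return [self.weight, self.bias]


class Conv1d(Layer):
    """1-d convolution (no padding) via an im2col patch matrix.

    Input  shape: (batch, in_channels, length)
    Output shape: (batch, out_channels, floor((length - kernel)/stride) + 1)
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator, dtype=np.float64) -> None:
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be positive")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        fan_in = in_channels * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale,
                                           (fan_in, out_channels)).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))
        self._patches: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def _out_length(self, length: int) -> int:
        return (length - self.kernel) // self.stride + 1

    def forward(self, x, train=True, rng=None):
        x = np.asarray(x, dtype=self.weight.value.dtype)
        b, c, length = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        lout = self._out_length(length)
        if lout < 1:
            raise ValueError("input shorter than kernel")
        # patches[b, t, c*k] = x[b, c, t*stride + k]
        idx = (np.arange(lout)[:, None] * self.stride + np.arange(self.kernel)[None, :])
        patches = x[:, :, idx]                      # (b, c, lout, k)
        patches = patches.transpose(0, 2, 1, 3).reshape(b, lout, c * self.kernel)
        self._patches = patches
        self._in_shape = x.shape
        out = patches @ self.weight.value + self.bias.value  # (b, lout, out_ch)
        return out.transpose(0, 2, 1)

    def backward(self, grad_out):
        b, _, lout = grad_out.shape
        g = grad_out.transpose(0, 2, 1)             # (b, lout, out_ch)
        self.weight.grad += np.tensordot(self._patches, g, axes=([0, 1], [0, 1]))
        self.bias.grad += g.sum(axis=(0, 1))
        gpatch = g @ self.weight.value.T            # (b, lout, c*k)
        gpatch = gpatch.reshape(b, lout, self.in_channels, self.kernel)
        gpatch = gpatch.transpose(0, 2, 1, 3)       # (b, c, lout, k)
        grad_x = np.zeros(self._in_shape, dtype=self.weight.value.dtype)
        # for a fixed kernel offset the target positions are a disjoint
        # strided slice, so the scatter-add reduces to slice accumulation
        for k in range(self.kernel):
            grad_x[:, :, k:k + self.stride * lout:self.stride] += gpatch[:, :, :, k]
        return grad_x

    def parameters(self):
        return [self.weight, self.bias]


class BatchNorm1d(Layer):
    """Batch normalization over the batch axis of a (batch, features) input.

    Train mode normalizes with minibatch statistics and updates running
    moments; eval mode uses the running moments.
    """

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float64) -> None:
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self._xhat: np.ndarray | None = None
        self._std: np.ndarray | None = None

    def forward(self, x, train=True, rng=None):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean = self.running_mean
            var = self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        self._xhat, self._std, self._train = xhat, std, train
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad_out):
        xhat, std = self._xhat, self._std
        self.gamma.grad += (grad_out * xhat).sum(axis=0)
        self.beta.grad += grad_out.sum(axis=0)
        dxhat = grad_out * self.gamma.value
        if not self._train:
            return dxhat / std
        n = grad_out.shape[0]
        return (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std

    def parameters(self):
        return [self.gamma, self.beta]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x, train=True, rng=None):
        # one float multiplier per entry: 1 where positive, slope elsewhere
        self._mask = np.where(x > 0, x.dtype.type(1.0), x.dtype.type(self.slope))
        return x * self._mask

    def backward(self, grad_out):
        return grad_out * self._mask


class Tanh(Layer):
    def forward(self, x, train=True, rng=None):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad_out):
        return grad_out * (1.0 - self._y ** 2)


class Dropout(Layer):
    """Inverted dropout: active only in train mode; needs an rng."""

    def __init__(self, rate: float) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | float = 1.0

    def forward(self, x, train=True, rng=None):
        if not train or self.rate == 0.0:
            self._mask = 1.0
            return x
        if rng is None:
            raise ValueError("Dropout in train mode requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, grad_out):
        return grad_out * self._mask


class Flatten(Layer):
    def forward(self, x, train=True, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x, train=True, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Adam:
    """Adam with the conventional bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 0.0095,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
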