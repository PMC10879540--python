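"""Learnable layers built on the autodiff engine.

Initialization is fan-based (Kaiming-uniform style) and drawn from an
explicit numpy Generator, so two builds from the same seed are bitwise
identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Module, Parameter, Tensor


def _kaiming_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_kaiming_uniform(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(rng.uniform(-1, 1, out_channels) / np.sqrt(fan_in)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)

    __call__ = forward


class Conv1d(Module):
    """1-D convolution over the last axis of a (N, Cin, L) tensor.

    Implemented as a 2-D convolution on a (N, Cin, 1, L) view.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        self.kernel_size = kernel_size
        self.padding = padding
        fan_in = in_channels * kernel_size
        self.weight = Parameter(_kaiming_uniform(
            rng, (out_channels, in_channels, 1, kernel_size), fan_in))
        self.bias = Parameter(rng.uniform(-1, 1, out_channels) / np.sqrt(fan_in)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        n, c, length = x.shape
        y = x.reshape(n, c, 1, length)
        # pad only along L: conv2d pads both dims, so pad manually via kernel height 1
        out = _conv2d_pad_w(y, self.weight, self.bias, self.padding)
        return out.reshape(out.shape[0], out.shape[1], out.shape[3])

    __call__ = forward


def _conv2d_pad_w(x: Tensor, weight, bias, pad_w: int) -> Tensor:
    """conv2d with padding applied to the width axis only (kernel height is 1)."""
    if pad_w == 0:
        return x.conv2d(weight, bias, stride=1, padding=0)
    n, c, h, w = x.shape
    zeros = Tensor(np.zeros((n, c, h, pad_w)))
    from .autodiff import concat
    xp = concat([zeros, x, zeros], axis=3)
    return xp.conv2d(weight, bias, stride=1, padding=0)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_kaiming_uniform(rng, (in_features, out_features), in_features))
        self.bias = Parameter(rng.uniform(-1, 1, out_features) / np.sqrt(in_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x.matmul(self.weight)
        return y + self.bias if self.bias is not None else y

    __call__ = forward


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        c = self.num_features
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(c) * (n / max(n - 1, 1))
            self._set_buffer("running_mean", (1 - self.momentum) * self.running_mean
                             + self.momentum * mu.data.reshape(c))
            self._set_buffer("running_var", (1 - self.momentum) * self.running_var
                             + self.momentum * unbiased)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)

    __call__ = forward


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x

    __call__ = forward
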