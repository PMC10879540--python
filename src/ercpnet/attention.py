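"""Channel and spatial attention blocks.

The adaptive channel attention (ACA) block gates feature maps with a
CBAM-style channel/spatial pair, but sizes its 1-D convolution kernel from
the channel count through the inverse of the Gaussian probability density:

    y = C / channel_normalizer
    x = sqrt(-2 sigma^2 * ln(y * sigma * sqrt(2*pi))) + mu

rounded to the nearest odd integer (ties away from zero) and floored at 1.
Wider feature maps therefore get *smaller* kernels: x decreases as the
normalized channel count y grows, and the function is only defined while
``y * sigma * sqrt(2*pi) <= 1`` (otherwise the logarithm flips sign and the
radicand is negative).

A standard CBAM block with a reduction-ratio MLP is provided as the ablation
baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Module, Tensor, concat
from .layers import Conv1d, Conv2d, Linear

__all__ = ["IGPDFParams", "igpdf_raw_size", "igpdf_kernel_size",
           "ChannelAttention", "SpatialAttention", "ACABlock", "CBAMBlock"]


@dataclass(frozen=True)
class IGPDFParams:
    """Parameters of the inverse-Gaussian-density kernel-size rule.

    mu: additive offset of the kernel size (kernel-size units).
    sigma: spread of the underlying Gaussian; must be positive.
    channel_normalizer: divisor mapping a raw channel count C to the density
        value y = C / channel_normalizer; must be positive.
    """

    mu: float = 0.0
    sigma: float = 1.0
    channel_normalizer: float = 2048.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.channel_normalizer <= 0:
            raise ValueError(f"channel_normalizer must be positive, got {self.channel_normalizer}")


def igpdf_raw_size(channel_count: int, params: IGPDFParams) -> float:
    """The continuous kernel size x before rounding.

    Inverts the Gaussian density at y = C / channel_normalizer.  Raises
    ValueError when y lies outside the density's range, i.e. when
    y * sigma * sqrt(2*pi) > 1 (the radicand would turn negative).
    """
    if channel_count < 1:
        raise ValueError(f"channel_count must be >= 1, got {channel_count}")
    y = channel_count / params.channel_normalizer
    arg = y * params.sigma * math.sqrt(2.0 * math.pi)
    if arg > 1.0:
        raise ValueError(
            f"channel count {channel_count} maps to density argument {arg:.6g} > 1; "
            f"increase channel_normalizer (= {params.channel_normalizer}) or sigma")
    radicand = -2.0 * params.sigma**2 * math.log(arg)
    return math.sqrt(radicand) + params.mu


def igpdf_kernel_size(channel_count: int, params: IGPDFParams) -> int:
    """Map a channel count to an odd 1-D convolution kernel size.

    Rounds the continuous inverse-density value to the nearest odd integer
    (ties away from zero) and floors it at 1.
    """
    x = igpdf_raw_size(channel_count, params)
    k = int(2 * math.floor((x - 1.0) / 2.0 + 0.5) + 1)  # nearest odd, ties away from 0
    return max(k, 1)


class ChannelAttention(Module):
    """Per-channel gate from pooled descriptors through two shared 1-D convs.

    Average- and max-pooled channel descriptors pass through the same pair of
    single-lane 1-D convolutions (ReLU between them, no downsampling); the
    branch outputs are summed and squashed with a sigmoid.
    """

    def __init__(self, kernel_size: int, *, rng: np.random.Generator):
        super().__init__()
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and >= 1, got {kernel_size}")
        self.kernel_size = kernel_size
        pad = (kernel_size - 1) // 2
        self.conv1 = Conv1d(1, 1, kernel_size, padding=pad, rng=rng)
        self.conv2 = Conv1d(1, 1, kernel_size, padding=pad, rng=rng)

    def _branch(self, desc: Tensor) -> Tensor:
        n, c = desc.shape
        h = self.conv1(desc.reshape(n, 1, c)).relu()
        return self.conv2(h).reshape(n, c)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))                      # (N, C)
        mx = x.max(axis=3).max(axis=2)                 # (N, C)
        if avg.shape != mx.shape:
            raise ValueError("pooled descriptor length mismatch")
        return (self._branch(avg) + self._branch(mx)).sigmoid()

    __call__ = forward


class SpatialAttention(Module):
    """Per-location gate: channel-wise mean/max maps through one 7x7 conv."""

    def __init__(self, kernel_size: int = 7, *, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel_size, padding=(kernel_size - 1) // 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] < 1 or x.shape[3] < 1:
            raise ValueError("spatial attention requires H, W >= 1")
        n, _, h, w = x.shape
        mean_map = x.mean(axis=1, keepdims=True)
        max_map = x.max(axis=1, keepdims=True)
        return self.conv(concat([mean_map, max_map], axis=1)).sigmoid()

    __call__ = forward


class ACABlock(Module):
    """Adaptive channel attention with a residual shortcut.

    combination='multiplicative' (default): gates are applied as multiplicative
    factors and added to the residual input,
        F' = F + M_S(w * F) * (w * F).
    combination='additive': the literal additive composition,
        F' = F + w + M_S(F),
    with the channel weights and the spatial map broadcast onto F.
    Both preserve the input shape exactly.
    """

    def __init__(self, channels: int, igpdf: IGPDFParams | None = None,
                 combination: str = "multiplicative", *, rng: np.random.Generator):
        super().__init__()
        if combination not in ("multiplicative", "additive"):
            raise ValueError(f"unknown combination mode: {combination!r}")
        self.channels = channels
        self.combination = combination
        self.igpdf = igpdf or IGPDFParams()
        self.kernel_size = igpdf_kernel_size(channels, self.igpdf)
        self.channel_att = ChannelAttention(self.kernel_size, rng=rng)
        self.spatial_att = SpatialAttention(rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        wch = self.channel_att(x).reshape(n, c, 1, 1)
        if self.combination == "multiplicative":
            gated = x * wch
            return x + self.spatial_att(gated) * gated
        return x + wch + self.spatial_att(x)

    __call__ = forward


class CBAMBlock(Module):
    """Convolutional block attention module (sequential channel then spatial gate).

    The channel gate uses a shared two-layer perceptron (C -> C/r -> C) on the
    average- and max-pooled descriptors.
    """

    def __init__(self, channels: int, reduction_ratio: int = 16, *,
                 rng: np.random.Generator):
        super().__init__()
        if channels % reduction_ratio != 0:
            raise ValueError(
                f"channels ({channels}) not divisible by reduction ratio ({reduction_ratio})")
        self.channels = channels
        hidden = channels // reduction_ratio
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)
        self.spatial_att = SpatialAttention(rng=rng)

    def _mlp(self, desc: Tensor) -> Tensor:
        return self.fc2(self.fc1(desc).relu())

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=3).max(axis=2)
        wch = (self._mlp(avg) + self._mlp(mx)).sigmoid().reshape(n, c, 1, 1)
        gated = x * wch
        return self.spatial_att(gated) * gated

    __call__ = forward
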