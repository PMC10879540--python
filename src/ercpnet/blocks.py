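"""Structural blocks: the stem, the channel-expansion residual (CER) block,
and the bidirectional information fusion (BIF) block.

The CER block triples the channel count *without parameters*: three parallel
max-pooling branches (windows 3/5/9, stride 2, paddings 1/2/4 so all agree
spatially) are concatenated along channels, then refined by a 1-3-1
convolution stack; a strided 1x1 projection carries the residual.  The BIF
block merges a mid-level map with an upsampled deep map, re-downsamples, and
re-merges with the deep map before a 1x1 expansion, combining pixel-level and
semantic information ahead of the classification head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Module, Tensor, concat
from .layers import BatchNorm2d, Conv2d, Identity

__all__ = ["CERConfig", "BIFConfig", "Stem", "CERBlock", "BIFBlock"]


@dataclass(frozen=True)
class CERConfig:
    in_channels: int
    pool_windows: tuple = (3, 5, 9)
    stride: int = 2
    use_batchnorm: bool = True

    def __post_init__(self):
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if any(w % 2 == 0 for w in self.pool_windows):
            raise ValueError(f"pool windows must be odd, got {self.pool_windows}")

    @property
    def out_channels(self) -> int:
        return len(self.pool_windows) * self.in_channels


@dataclass(frozen=True)
class BIFConfig:
    mid_channels: int      # C2, the shallower input
    deep_channels: int     # C3, the deeper input (half the spatial size)
    out_channels: int | None = None   # defaults to 3 * deep_channels
    upsample_mode: str = "nearest"

    def __post_init__(self):
        if self.mid_channels < 1 or self.deep_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.upsample_mode not in ("nearest", "bilinear"):
            raise ValueError(f"unknown upsample mode: {self.upsample_mode!r}")
        if self.resolved_out_channels < self.deep_channels:
            raise ValueError("out_channels must be >= deep_channels")

    @property
    def resolved_out_channels(self) -> int:
        return self.out_channels if self.out_channels is not None else 3 * self.deep_channels


class Stem(Module):
    """7x7 stride-2 convolution (BN + ReLU) followed by a 3x3 stride-2 max-pool.

    Quarters the spatial dimensions and lifts 3 input channels to stem_width.
    """

    def __init__(self, stem_width: int = 16, *, rng: np.random.Generator):
        super().__init__()
        self.stem_width = stem_width
        self.conv = Conv2d(3, stem_width, 7, stride=2, padding=3, bias=False, rng=rng)
        self.bn = BatchNorm2d(stem_width)

    def conv_forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != 3:
            raise ValueError(f"stem expects 3 input channels, got {x.shape[1]}")
        return self.bn(self.conv(x)).relu()

    def forward(self, x: Tensor) -> Tensor:
        return self.conv_forward(x).maxpool2d(3, stride=2, padding=1)

    __call__ = forward


class CERBlock(Module):
    def __init__(self, config: CERConfig, *, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c3 = config.out_channels
        bn = BatchNorm2d if config.use_batchnorm else (lambda c: Identity())
        self.agg_conv1 = Conv2d(c3, c3, 1, bias=False, rng=rng)
        self.agg_bn1 = bn(c3)
        self.agg_conv2 = Conv2d(c3, c3, 3, padding=1, bias=False, rng=rng)
        self.agg_bn2 = bn(c3)
        self.agg_conv3 = Conv2d(c3, c3, 1, bias=False, rng=rng)
        self.agg_bn3 = bn(c3)
        self.res_conv = Conv2d(config.in_channels, c3, 1, stride=config.stride,
                               bias=False, rng=rng)
        self.res_bn = bn(c3)

    def expand(self, x: Tensor) -> Tensor:
        """Parameter-free channel expansion: parallel max-pools, concatenated."""
        branches = []
        for w in self.config.pool_windows:
            branches.append(x.maxpool2d(w, stride=self.config.stride, padding=(w - 1) // 2))
        return concat(branches, axis=1)

    def expansion_param_count(self) -> int:
        """Learnable parameters of the pooling/concatenation stage: always 0."""
        return 0

    def param_count(self) -> int:
        return self.num_parameters()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"CER block expects {self.config.in_channels} channels, got {x.shape[1]}")
        if min(x.shape[2], x.shape[3]) < 2:
            raise ValueError("input spatial dims too small for stride-2 pooling")
        h = self.expand(x)
        h = self.agg_bn1(self.agg_conv1(h)).relu()
        h = self.agg_bn2(self.agg_conv2(h)).relu()
        h = self.agg_bn3(self.agg_conv3(h))
        res = self.res_bn(self.res_conv(x))
        return (h + res).relu()

    __call__ = forward


class BIFBlock(Module):
    def __init__(self, config: BIFConfig, *, rng: np.random.Generator):
        super().__init__()
        self.config = config
        merged = config.deep_channels + config.mid_channels
        self.fuse_conv = Conv2d(merged + config.deep_channels,
                                config.resolved_out_channels, 1, bias=False, rng=rng)
        self.fuse_bn = BatchNorm2d(config.resolved_out_channels)

    def forward(self, p2: Tensor, p3: Tensor) -> Tensor:
        cfg = self.config
        if p2.shape[1] != cfg.mid_channels or p3.shape[1] != cfg.deep_channels:
            raise ValueError(
                f"BIF expects channels ({cfg.mid_channels}, {cfg.deep_channels}); "
                f"got ({p2.shape[1]}, {p3.shape[1]})")
        up = p3.upsample2x(mode=cfg.upsample_mode)
        if up.shape[2:] != p2.shape[2:]:
            raise ValueError(
                f"upsampled deep map {up.shape[2:]} does not match mid map {p2.shape[2:]}; "
                "the deep input must be exactly half the mid input spatially")
        merged = concat([up, p2], axis=1)
        down = merged.maxpool2d(3, stride=2, padding=1)
        fused = concat([down, p3], axis=1)
        return self.fuse_bn(self.fuse_conv(fused)).relu()

    __call__ = forward
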