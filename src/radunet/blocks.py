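"""Reusable network blocks: residual unit, CBAM attention, improved ASPP.

The channel attention module (CAM) weights each feature channel by

    Mc(F) = sigmoid( MLP(AvgPool(F)) + MLP(MaxPool(F)) )

where the MLP is a shared two-layer bottleneck W1·ReLU(W0·x) with
W0 ∈ R^{C/r×C}, W1 ∈ R^{C×C/r} and reduction ratio r.  The spatial
attention module (SAM) weights each location by

    Ms(F) = sigmoid( f_{k×k}([AvgPool_c(F); MaxPool_c(F)]) )

with a single k×k convolution (k = 7 by convention) over the
channel-pooled average and max maps.  CBAM applies CAM then SAM
multiplicatively.

The improved atrous spatial pyramid pooling (ASPP) head runs five
parallel branches — a 1×1 convolution, three 3×3 dilated convolutions
at small rates tuned for small lesions, and image-level average
pooling — and projects the concatenation back to the target width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Module, Conv2d, Tensor,
    broadcast_hw, concat, maxpool2x2, mul, reduce_max, reduce_mean, relu, sigmoid,
)


@dataclass(frozen=True)
class AttentionConfig:
    """CBAM hyperparameters.

    reduction_ratio is the channel-MLP bottleneck divisor (the CBAM
    convention is 16); spatial_kernel is the SAM convolution size and
    must be odd.
    """

    channels: int
    reduction_ratio: int = 16
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")
        if self.spatial_kernel % 2 == 0 or self.spatial_kernel < 1:
            raise ValueError(f"spatial_kernel must be odd and positive, got {self.spatial_kernel}")

    @property
    def bottleneck(self) -> int:
        return max(1, self.channels // self.reduction_ratio)


@dataclass(frozen=True)
class ASPPConfig:
    """Dilation rates of the three 3x3 branches and the output width."""

    rates: tuple[int, ...] = (2, 3, 4)
    out_channels: int = 64

    def __post_init__(self):
        if len(self.rates) == 0:
            raise ValueError("at least one dilation rate required")
        if len(set(self.rates)) != len(self.rates):
            raise ValueError("dilation rates must be distinct")
        if any((not isinstance(r, (int, np.integer))) or r < 1 for r in self.rates):
            raise ValueError("dilation rates must be positive integers")


def stacked_receptive_field(kernel: int, rates: tuple[int, ...] | list[int]) -> tuple[int, ...]:
    """Receptive-field side length after each layer of a dilated cascade.

    Stacking k×k convolutions with dilation rates r_1, r_2, ... grows the
    receptive field cumulatively:

        RF_0 = 1,   RF_i = RF_{i-1} + (k - 1) * r_i

    e.g. a 3×3 cascade at rates (1, 2, 4) sees 3×3, then 7×7, then 15×15.
    Returns the sequence (RF_1, ..., RF_n).
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and positive, got {kernel}")
    rates = tuple(rates)
    if not rates:
        raise ValueError("rates must be non-empty")
    if any(r < 1 for r in rates):
        raise ValueError("rates must be positive")
    rf = 1
    out = []
    for r in rates:
        rf += (kernel - 1) * int(r)
        out.append(rf)
    return tuple(out)


class ResidualBlock(Module):
    """Two 3×3 convolutions plus a shortcut, rectified on the way out.

    The shortcut is the identity when channel counts match and a 1×1
    projection otherwise.  Stride is always 1; spatial size is preserved.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng)
        self.shortcut = None if in_channels == out_channels else Conv2d(in_channels, out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(relu(self.conv1(x)))
        s = x if self.shortcut is None else self.shortcut(x)
        return relu(y + s)


class ChannelAttention(Module):
    """CAM: shared bottleneck MLP over global average- and max-pooled descriptors."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        self.cfg = cfg
        # the shared MLP acts on 1x1xC descriptors, expressed as 1x1 convs
        self.w0 = Conv2d(cfg.channels, cfg.bottleneck, 1, rng)
        self.w1 = Conv2d(cfg.bottleneck, cfg.channels, 1, rng)

    def _mlp(self, d: Tensor) -> Tensor:
        return self.w1(relu(self.w0(d)))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(f"expected {self.cfg.channels} channels, got {x.shape[1]}")
        avg = reduce_mean(x, axes=(2, 3), keepdims=True)
        mx = reduce_max(x, axes=(2, 3), keepdims=True)
        return sigmoid(self._mlp(avg) + self._mlp(mx))


class SpatialAttention(Module):
    """SAM: one wide convolution over the channel-pooled [avg; max] maps."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.conv = Conv2d(2, 1, cfg.spatial_kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = reduce_mean(x, axes=(1,), keepdims=True)
        mx = reduce_max(x, axes=(1,), keepdims=True)
        return sigmoid(self.conv(concat([avg, mx], axis=1)))


class CBAM(Module):
    """Channel attention then spatial attention, each applied multiplicatively."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        self.cam = ChannelAttention(cfg, rng)
        self.sam = SpatialAttention(cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        xc = mul(self.cam(x), x)
        return mul(self.sam(xc), xc)


class ASPP(Module):
    """Improved ASPP: 1×1 conv + three dilated 3×3 convs + image pooling.

    All branches preserve spatial size (dilated branches use padding equal
    to their rate); the five outputs are concatenated on channels and
    projected to ``cfg.out_channels`` by a 1×1 convolution.
    """

    def __init__(self, in_channels: int, cfg: ASPPConfig, rng: np.random.Generator):
        self.cfg = cfg
        c = cfg.out_channels
        self.branch1x1 = Conv2d(in_channels, c, 1, rng)
        self.dilated = [Conv2d(in_channels, c, 3, rng, dilation=int(r)) for r in cfg.rates]
        self.pool_conv = Conv2d(in_channels, c, 1, rng)
        self.project = Conv2d(c * (len(cfg.rates) + 2), c, 1, rng)

    @property
    def n_branches(self) -> int:
        return len(self.cfg.rates) + 2

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        outs = [relu(self.branch1x1(x))]
        outs += [relu(b(x)) for b in self.dilated]
        pooled = reduce_mean(x, axes=(2, 3), keepdims=True)
        outs.append(broadcast_hw(relu(self.pool_conv(pooled)), h, w))
        return relu(self.project(concat(outs, axis=1)))
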