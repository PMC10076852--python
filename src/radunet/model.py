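"""RAD-UNet assembly: residual encoder, ASPP bottleneck, DFCF decoder.

The network is a U-shaped encoder-decoder for binary lesion maps:

* encoder — four stages of two residual blocks each, channel width
  doubling per stage, 2x2 max pooling between stages;
* bottleneck — one improved ASPP head capturing multiscale context at
  the coarsest resolution;
* decoder — four stages; each upsamples bilinearly, projects channels,
  and fuses the upsampled *global semantic features* (GSF) with the
  encoder skip's *local semantic features* (LSF) through a dual-feature
  cross-fusion (DFCF) module, then refines with a residual block;
* head — 1x1 convolution + sigmoid giving a per-pixel lesion
  probability in (0, 1); spatial size always equals the input's.

DFCF is the cross-attention fusion: channel-attention weights computed
from one stream are applied to the other, in both directions, each
branch then passing through spatial attention; the two branches are
combined by concatenation + 1x1 convolution (or summation).  The CAM and
SAM parameters are shared between the two branches, which makes the
module symmetric: identical input streams give identical branches.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .blocks import ASPP, ASPPConfig, AttentionConfig, CBAM, ChannelAttention, ResidualBlock, SpatialAttention
from .nn import (
    Conv2d, Module, Tensor,
    concat, maxpool2x2, mul, relu, sigmoid, upsample_bilinear2x,
)


@dataclass(frozen=True)
class RADUNetConfig:
    """Architecture hyperparameters.

    ``base_channels`` is the width of the first encoder stage; each of
    the ``n_down`` stages doubles it.  ``blocks_per_stage=2`` gives a
    ResNet-18-like encoder.  Input sides must be divisible by 2**n_down.
    """

    base_channels: int = 64
    n_down: int = 4
    blocks_per_stage: int = 2
    aspp_rates: tuple[int, ...] = (2, 3, 4)
    attention_reduction: int = 16
    spatial_kernel: int = 7
    dfcf_combine: str = "concat"      # "concat" | "sum"
    dfcf_sam_source: str = "self"     # "self" | "other"
    residual_encoder: bool = True     # False -> plain double-conv (U-Net baseline)
    use_attention: bool = True        # False -> decoder fuses by concat only
    out_classes: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_down < 1:
            raise ValueError("n_down must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.dfcf_combine not in ("concat", "sum"):
            raise ValueError("dfcf_combine must be 'concat' or 'sum'")
        if self.dfcf_sam_source not in ("self", "other"):
            raise ValueError("dfcf_sam_source must be 'self' or 'other'")
        if self.out_classes != 1:
            raise ValueError("only binary segmentation (out_classes=1) is supported")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["aspp_rates"] = list(self.aspp_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RADUNetConfig":
        d = dict(d)
        if "aspp_rates" in d:
            d["aspp_rates"] = tuple(int(r) for r in d["aspp_rates"])
        return cls(**d)


class DoubleConv(Module):
    """Plain two-convolution stage (the classic U-Net building block)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.conv2(relu(self.conv1(x))))


class DFCF(Module):
    """Dual-feature cross-fusion of an encoder skip (LSF) and the decoder stream (GSF).

    Branch A applies channel weights computed from the LSF to the GSF;
    branch B applies channel weights computed from the GSF to the LSF.
    Each branch then passes through spatial attention — by default the
    spatial weights are computed from the branch's own product map
    (``sam_source='self'``); ``'other'`` computes them from the opposite
    input stream instead.  CAM/SAM parameters are shared across branches.
    """

    def __init__(self, channels: int, cfg: RADUNetConfig, rng: np.random.Generator):
        acfg = AttentionConfig(channels, cfg.attention_reduction, cfg.spatial_kernel)
        self.cam = ChannelAttention(acfg, rng)
        self.sam = SpatialAttention(acfg, rng)
        self.combine = cfg.dfcf_combine
        self.sam_source = cfg.dfcf_sam_source
        self.proj = Conv2d(2 * channels, channels, 1, rng) if self.combine == "concat" else None

    def _branch(self, weight_source: Tensor, target: Tensor) -> Tensor:
        prod = mul(self.cam(weight_source), target)
        sam_input = prod if self.sam_source == "self" else weight_source
        return mul(self.sam(sam_input), prod)

    def forward(self, lsf: Tensor, gsf: Tensor) -> Tensor:
        if lsf.shape != gsf.shape:
            raise ValueError(f"LSF {lsf.shape} and GSF {gsf.shape} must share shape")
        a = self._branch(lsf, gsf)
        b = self._branch(gsf, lsf)
        if self.combine == "sum":
            return a + b
        return self.proj(concat([a, b], axis=1))


class _DecoderStage(Module):
    def __init__(self, in_channels: int, out_channels: int, cfg: RADUNetConfig,
                 rng: np.random.Generator):
        self.project = Conv2d(in_channels, out_channels, 1, rng)
        self.fuse = DFCF(out_channels, cfg, rng) if cfg.use_attention else None
        merge_in = out_channels if cfg.use_attention else 2 * out_channels
        block = ResidualBlock if cfg.residual_encoder else DoubleConv
        self.refine = block(merge_in, out_channels, rng)

    def forward(self, deep: Tensor, skip: Tensor) -> Tensor:
        up = self.project(upsample_bilinear2x(deep))
        if self.fuse is not None:
            merged = self.fuse(skip, up)
        else:
            merged = concat([skip, up], axis=1)
        return self.refine(merged)


class RADUNet(Module):
    """The assembled segmentation network: input N×1×H×W, output N×1×H×W in (0,1)."""

    def __init__(self, cfg: RADUNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.base_channels
        block = ResidualBlock if cfg.residual_encoder else DoubleConv

        widths = [c * 2 ** i for i in range(cfg.n_down)]
        self.encoder_stages = []
        in_ch = 1
        for w in widths:
            stage = [block(in_ch, w, rng)]
            stage += [block(w, w, rng) for _ in range(cfg.blocks_per_stage - 1)]
            self.encoder_stages.append(stage)
            in_ch = w

        bottleneck_ch = c * 2 ** cfg.n_down
        self.bottleneck_block = block(in_ch, bottleneck_ch, rng)
        self.aspp = ASPP(bottleneck_ch, ASPPConfig(cfg.aspp_rates, bottleneck_ch), rng)

        self.decoder_stages = []
        deep_ch = bottleneck_ch
        for w in reversed(widths):
            self.decoder_stages.append(_DecoderStage(deep_ch, w, cfg, rng))
            deep_ch = w
        self.head = Conv2d(deep_ch, cfg.out_classes, 1, rng)

    # -- structural introspection --------------------------------------
    @property
    def n_dfcf(self) -> int:
        return sum(1 for s in self.decoder_stages if s.fuse is not None)

    @property
    def n_aspp(self) -> int:
        return 1

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected N x 1 x H x W input, got {x.shape}")
        h, w = x.shape[2], x.shape[3]
        d = 2 ** self.cfg.n_down
        if h % d or w % d:
            raise ValueError(
                f"input side {h}x{w} must be divisible by 2**n_down = {d} "
                f"for {self.cfg.n_down} downsampling stages"
            )
        skips = []
        for stage in self.encoder_stages:
            for blk in stage:
                x = blk(x)
            skips.append(x)
            x = maxpool2x2(x)
        x = self.aspp(self.bottleneck_block(x))
        for stage, skip in zip(self.decoder_stages, reversed(skips)):
            x = stage(x, skip)
        return sigmoid(self.head(x))

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Probability map for a single H×W image (no gradient tape)."""
        x = np.asarray(image, dtype=np.float32)[None, None]
        return self.forward(Tensor(x)).data[0, 0]


def build_radunet(cfg: RADUNetConfig) -> RADUNet:
    """Build a RAD-UNet; deterministic for a fixed config (incl. its seed)."""
    return RADUNet(cfg)


def segment(model: RADUNet, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize the model's probability map at ``threshold``.

    The image must be normalized to [0, 1]; out-of-range values trigger a
    warning and are clipped.  Returns a uint8 mask.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    image = np.asarray(image, dtype=np.float32)
    tol = 1e-3
    if image.min() < -tol or image.max() > 1.0 + tol:
        warnings.warn(
            f"input range [{image.min():.3g}, {image.max():.3g}] is not normalized; clipping",
            stacklevel=2,
        )
    image = np.clip(image, 0.0, 1.0)
    proba = model.predict_proba(image)
    return (proba >= threshold).astype(np.uint8)


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(path, model: RADUNet) -> None:
    """Persist parameters + config to an .npz archive."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> RADUNet:
    with np.load(path) as data:
        cfg = RADUNetConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
        model = RADUNet(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
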