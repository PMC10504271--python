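"""Multi-scale convolutional encoder (stem + MBConv stages with SE).

The encoder follows the mobile-inverted-bottleneck family: a stride-2 stem
convolution, then five MBConv stages whose first block may downsample.
Feature maps are tapped at five points — after the stem and after stages
2..5 — giving a pyramid at strides 2, 4, 8, 16 and 32 of the input side
(e.g. 256 -> 128/64/32/16/8).  Channel widths, depths, kernel sizes, the
expansion ratio and the squeeze-and-excitation ratio are all configuration,
with two presets:

``tiny``
    a sub-0.5M-parameter variant for desk-scale training and tests;
``b5like``
    widths/depths in the spirit of the large end of the family.

Weight initialisation is fan-out-scaled normal, fixed by a seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor
from .nn import autodiff as ad

STRIDES = (2, 4, 8, 16, 32)


@dataclasses.dataclass
class FeatureMap:
    """One pyramid level: values C_i x H_i x W_i at a fixed stride."""

    values: np.ndarray
    level: int
    stride: int

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("feature map must be C x H x W")
        if self.stride not in STRIDES:
            raise ValueError(f"stride must be one of {STRIDES}")


@dataclasses.dataclass
class FeaturePyramid:
    """Ordered five-level pyramid with strictly increasing strides."""

    levels: list[FeatureMap]

    def __post_init__(self):
        if len(self.levels) != 5:
            raise ValueError(f"expected 5 levels, got {len(self.levels)}")
        if tuple(f.stride for f in self.levels) != STRIDES:
            raise ValueError("level strides must be (2, 4, 8, 16, 32)")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(f.values.shape[0] for f in self.levels)


@dataclasses.dataclass(frozen=True)
class EncoderConfig:
    stage_channels: tuple[int, ...] = (8, 8, 16, 24, 32, 48)  # stem + 5 stages
    stage_depths: tuple[int, ...] = (1, 1, 1, 1, 1)
    stage_kernels: tuple[int, ...] = (3, 3, 3, 3, 3)
    expansion_ratio: int = 2
    se_ratio: float = 0.25
    preset: str = "tiny"

    def __post_init__(self):
        if len(self.stage_channels) != 6:
            raise ValueError("stage_channels must list stem + 5 stage widths")
        if len(self.stage_depths) != 5 or len(self.stage_kernels) != 5:
            raise ValueError("stage_depths and stage_kernels must have 5 entries")
        if any(c < 4 for c in self.stage_channels):
            raise ValueError("all channel counts must be >= 4")
        if any(d < 1 for d in self.stage_depths):
            raise ValueError("all stage depths must be >= 1")
        if self.expansion_ratio < 1:
            raise ValueError("expansion_ratio must be >= 1")
        if not 0.0 < self.se_ratio <= 1.0:
            raise ValueError("se_ratio must be in (0, 1]")

    @staticmethod
    def preset_tiny() -> "EncoderConfig":
        return EncoderConfig()

    @staticmethod
    def preset_b5like() -> "EncoderConfig":
        return EncoderConfig(
            stage_channels=(48, 24, 40, 64, 176, 512),
            stage_depths=(3, 5, 5, 7, 9),
            stage_kernels=(3, 3, 5, 3, 5),
            expansion_ratio=6,
            se_ratio=0.25,
            preset="b5like",
        )

    @staticmethod
    def from_preset(name: str) -> "EncoderConfig":
        try:
            return {"tiny": EncoderConfig.preset_tiny,
                    "b5like": EncoderConfig.preset_b5like}[name]()
        except KeyError:
            raise ValueError(f"unknown encoder preset {name!r}") from None


class Encoder(nn.Module):
    """Stem + five MBConv stages; ``forward`` returns the five taps."""

    def __init__(self, cfg: EncoderConfig, *, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        ch = cfg.stage_channels
        self.stem = nn.Conv2d(1, ch[0], 3, stride=2, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(ch[0])
        stages = []
        in_c = ch[0]
        # stage 1 keeps stride 2; stages 2..5 each downsample once
        stage_strides = (1, 2, 2, 2, 2)
        for s in range(5):
            blocks = []
            for d in range(cfg.stage_depths[s]):
                blocks.append(nn.MBConv(
                    in_c, ch[s + 1], k=cfg.stage_kernels[s],
                    stride=stage_strides[s] if d == 0 else 1,
                    expansion_ratio=cfg.expansion_ratio,
                    se_ratio=cfg.se_ratio, rng=rng,
                ))
                in_c = ch[s + 1]
            stages.append(nn.ModuleList(blocks))
        self.stages = nn.ModuleList(stages)

    def forward(self, x: Tensor) -> list[Tensor]:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected input N x 1 x S x S, got {x.shape}")
        side = x.shape[2]
        if side % 32 or x.shape[3] % 32:
            raise ValueError(f"input sides must be divisible by 32, got "
                             f"{x.shape[2]}x{x.shape[3]}")
        h = ad.swish(self.stem_bn(self.stem(x)))
        taps = [h]
        for s, stage in enumerate(self.stages):
            for block in stage:
                h = block(h)
            if s >= 1:  # taps after stem and stages 2..5
                taps.append(h)
        return taps


def build_encoder(cfg: EncoderConfig, seed: int = 0) -> Encoder:
    """Construct an encoder with seeded weight initialisation."""
    return Encoder(cfg, rng=np.random.default_rng(seed))


def encode(enc: Encoder, img: np.ndarray) -> FeaturePyramid:
    """Run one normalized S x S image through the encoder (inference mode)."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("encode expects a single 2-D image")
    was_training = enc.training
    enc.eval()
    try:
        with ad.no_grad():
            taps = enc(Tensor(img[None, None]))
    finally:
        enc.train(was_training)
    return FeaturePyramid([
        FeatureMap(values=t.data[0], level=i + 1, stride=STRIDES[i])
        for i, t in enumerate(taps)
    ])
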