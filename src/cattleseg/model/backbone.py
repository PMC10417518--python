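"""Truncated MobileNetV2 feature extractor.

Only the feature-extraction stages are kept (no classifier head). Each
bottleneck is an inverted residual: 1×1 expansion, 3×3 depthwise
convolution, linear 1×1 projection, with a skip connection when the block
neither strides nor changes width. The two deepest stage groups run at
stride 1 — the last one with dilated depthwise kernels — so the deepest
map keeps 1/16 resolution while the receptive field still grows.

``forward`` returns the feature maps tapped at down-sampling factors
2, 4 and 8 (the last map produced at each resolution) plus the deepest
1/16 map, which is what the decoder fuses.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .. import nn
from ..exceptions import DimensionError
from .config import BackboneConfig, StageSpec

__all__ = ["InvertedResidual", "MobileNetV2Backbone", "classifier_head_param_count"]


class InvertedResidual(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, expansion: int, stride: int,
                 dilation: int, rng: np.random.Generator):
        super().__init__()
        self.use_residual = stride == 1 and in_ch == out_ch
        hidden = in_ch * expansion
        if expansion != 1:
            self.expand = nn.Sequential(
                nn.Conv2d(in_ch, hidden, 1, rng=rng),
                nn.BatchNorm2d(hidden), nn.ReLU6())
        else:
            self.expand = nn.Identity()
        self.depthwise = nn.Sequential(
            nn.DepthwiseConv2d(hidden, 3, stride=stride, dilation=dilation, rng=rng),
            nn.BatchNorm2d(hidden), nn.ReLU6())
        # linear bottleneck: no activation after the projection
        self.project = nn.Sequential(
            nn.Conv2d(hidden, out_ch, 1, rng=rng), nn.BatchNorm2d(out_ch))

    def forward(self, x):
        y = self.project(self.depthwise(self.expand(x)))
        if self.use_residual:
            y = nn.functional.add(y, x)
        return y


class MobileNetV2Backbone(nn.Module):
    """Stem convolution plus the configured bottleneck stage groups."""

    def __init__(self, config: Optional[BackboneConfig] = None,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.config = config or BackboneConfig()
        rng = rng or np.random.default_rng()
        cfg = self.config
        self.stem = nn.Sequential(
            nn.Conv2d(3, cfg.stem_channels, 3, stride=cfg.stem_stride, rng=rng),
            nn.BatchNorm2d(cfg.stem_channels), nn.ReLU6())
        in_ch = cfg.stem_channels
        self._block_meta = []  # (factor after this block,)
        factor = cfg.stem_stride
        blocks = []
        for spec in cfg.stages:
            for i in range(spec.repeats_n):
                stride = spec.stride_s if i == 0 else 1
                factor *= stride
                blocks.append(InvertedResidual(in_ch, spec.out_channels_c,
                                               spec.expansion_t, stride,
                                               spec.dilation_rate, rng))
                self._block_meta.append(factor)
                in_ch = spec.out_channels_c
        self.blocks = nn.Sequential(*blocks)
        self.out_channels = in_ch

    def forward(self, x) -> Dict[int, nn.Tensor]:
        """Run the extractor; returns {factor: feature map} for each tap
        level plus the deepest map under its own factor."""
        x = nn.as_tensor(x) if not isinstance(x, nn.Tensor) else x
        n, h, w, c = x.data.shape
        os_ = self.config.output_stride
        if h % os_:
            raise DimensionError(f"input height {h} not divisible by {os_}")
        if w % os_:
            raise DimensionError(f"input width {w} not divisible by {os_}")
        taps: Dict[int, nn.Tensor] = {}
        y = self.stem(x)
        factor = self.config.stem_stride
        taps[factor] = y
        for block, f_after in zip(self.blocks, self._block_meta):
            y = block(y)
            taps[f_after] = y  # later maps at the same factor overwrite earlier
        taps[self._block_meta[-1]] = y
        wanted = set(self.config.tap_levels) | {self.config.output_stride}
        return {f: t for f, t in taps.items() if f in wanted}

    def tapped_channels(self) -> Dict[int, int]:
        """Channel count of the feature map returned at each factor."""
        chans: Dict[int, int] = {self.config.stem_stride: self.config.stem_channels}
        factor = self.config.stem_stride
        for spec in self.config.stages:
            factor *= spec.stride_s
            chans[factor] = spec.out_channels_c
        wanted = set(self.config.tap_levels) | {self.config.output_stride}
        return {f: c for f, c in chans.items() if f in wanted}


def classifier_head_param_count(config: Optional[BackboneConfig] = None,
                                n_classes: int = 1000) -> int:
    """Parameters the un-truncated classification network would add on
    top of the feature stages: the 1×1 expansion to 1280 channels (with
    batch norm) and the fully connected classifier."""
    cfg = config or BackboneConfig()
    c_last = cfg.out_channels
    conv = c_last * 1280 + 2 * 1280          # 1x1 conv + BN gamma/beta
    fc = 1280 * n_classes + n_classes
    return conv + fc
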