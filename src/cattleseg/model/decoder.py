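"""Decoders.

``LayerwiseDecoder`` is the improved design: the encoder output is raised
back to input resolution through four 2× bilinear up-samplings with three
fusion points, one per tapped backbone resolution (1/8, 1/4, 1/2). Each
fusion concatenates the up-sampled deep features with a 1×1-reduced
low-level map; an optional squeeze-and-excitation block reweights the
fused channels. The first two fusions are refined by a 3×3
conv–BN–ReLU; after the last fusion two 3×3 conv layers are stacked to
deepen the decoder without losing resolution, followed by the 1×1
classifier and a final 2× up-sampling of the logits.

``SimpleDecoder`` is the original single-fusion design: one 4×
up-sampling, fusion with the 1/4 map, refinement, classifier, and a
second 4× up-sampling.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from .. import nn
from ..exceptions import ConfigurationError
from .config import ModelVariant, SEBlockSpec
from .se import SEBlock

__all__ = ["LayerwiseDecoder", "SimpleDecoder", "build_decoder"]


def _conv_bn_relu(cin, cout, k, rng):
    return nn.Sequential(nn.Conv2d(cin, cout, k, rng=rng),
                         nn.BatchNorm2d(cout), nn.ReLU())


class LayerwiseDecoder(nn.Module):
    #: up-sampling factors applied in order (all bilinear)
    upsample_factors = (2, 2, 2, 2)
    n_fusions = 3

    def __init__(self, aspp_channels: int, tapped_channels: Dict[int, int],
                 num_classes: int, use_se: bool = True,
                 low_channels: int = 48, refine_channels: int = 256,
                 se_reduction: int = 16,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        for f in (8, 4, 2):
            if f not in tapped_channels:
                raise ConfigurationError(
                    f"layerwise decoder needs tapped maps at factors 8, 4, 2; missing {f}")
        rng = rng or np.random.default_rng()
        self.use_se = use_se
        self.num_classes = num_classes
        self.refine_channels = refine_channels
        widths = [aspp_channels, refine_channels, refine_channels]
        for i, f in enumerate((8, 4, 2)):
            setattr(self, f"reduce{f}",
                    _conv_bn_relu(tapped_channels[f], low_channels, 1, rng))
            fused = widths[i] + low_channels
            if use_se:
                setattr(self, f"se{f}", SEBlock(SEBlockSpec(fused, se_reduction), rng))
        self.refine8 = _conv_bn_relu(aspp_channels + low_channels, refine_channels, 3, rng)
        self.refine4 = _conv_bn_relu(refine_channels + low_channels, refine_channels, 3, rng)
        # after the last fusion: two stacked 3x3 conv layers
        self.stack1 = _conv_bn_relu(refine_channels + low_channels, refine_channels, 3, rng)
        self.stack2 = _conv_bn_relu(refine_channels, refine_channels, 3, rng)
        self.classifier = nn.Conv2d(refine_channels, num_classes, 1, bias=True, rng=rng)

    def _fuse(self, deep, factor):
        low = getattr(self, f"reduce{factor}")(getattr(self, "_taps")[factor])
        fused = nn.functional.concat([deep, low], axis=-1)
        if self.use_se:
            fused = getattr(self, f"se{factor}")(fused)
        return fused

    def forward(self, aspp_out, taps: Dict[int, nn.Tensor]):
        object.__setattr__(self, "_taps", taps)
        up = nn.functional.upsample_bilinear
        y = up(aspp_out, 2)                       # 1/16 -> 1/8
        y = self.refine8(self._fuse(y, 8))
        y = up(y, 2)                              # 1/8 -> 1/4
        y = self.refine4(self._fuse(y, 4))
        y = up(y, 2)                              # 1/4 -> 1/2
        y = self.stack2(self.stack1(self._fuse(y, 2)))
        logits = self.classifier(y)
        return up(logits, 2)                      # 1/2 -> 1/1


class SimpleDecoder(nn.Module):
    upsample_factors = (4, 4)
    n_fusions = 1

    def __init__(self, aspp_channels: int, tapped_channels: Dict[int, int],
                 num_classes: int, low_channels: int = 48,
                 refine_channels: int = 256,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        if 4 not in tapped_channels:
            raise ConfigurationError("simple decoder needs a tapped map at factor 4")
        rng = rng or np.random.default_rng()
        self.num_classes = num_classes
        self.reduce4 = _conv_bn_relu(tapped_channels[4], low_channels, 1, rng)
        self.refine = nn.Sequential(
            _conv_bn_relu(aspp_channels + low_channels, refine_channels, 3, rng),
            _conv_bn_relu(refine_channels, refine_channels, 3, rng))
        self.classifier = nn.Conv2d(refine_channels, num_classes, 1, bias=True, rng=rng)

    def forward(self, aspp_out, taps: Dict[int, nn.Tensor]):
        up = nn.functional.upsample_bilinear
        y = up(aspp_out, 4)                       # 1/16 -> 1/4
        low = self.reduce4(taps[4])
        y = self.refine(nn.functional.concat([y, low], axis=-1))
        return up(self.classifier(y), 4)          # 1/4 -> 1/1


def build_decoder(variant: ModelVariant, aspp_channels: int,
                  tapped_channels: Dict[int, int], *, low_channels: int = 48,
                  refine_channels: int = 256, se_reduction: int = 16,
                  rng: Optional[np.random.Generator] = None):
    """Construct the decoder matching a model variant."""
    if variant.decoder_style == "layerwise":
        return LayerwiseDecoder(aspp_channels, tapped_channels, variant.num_classes,
                                use_se=variant.use_se, low_channels=low_channels,
                                refine_channels=refine_channels,
                                se_reduction=se_reduction, rng=rng)
    return SimpleDecoder(aspp_channels, tapped_channels, variant.num_classes,
                         low_channels=low_channels, refine_channels=refine_channels,
                         rng=rng)
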