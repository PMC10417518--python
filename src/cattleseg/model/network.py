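"""Full segmentation network: backbone → ASPP → decoder.

``build_model`` wires a variant together; checkpoints embed the full
configuration so evaluation can reconstruct the exact variant from the
file alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .. import nn
from .aspp import ASPP
from .backbone import MobileNetV2Backbone
from .config import BackboneConfig, ModelVariant
from .decoder import build_decoder

__all__ = ["NetworkWidths", "SegmentationNetwork", "build_model",
           "save_checkpoint", "load_checkpoint", "DESK_WIDTHS"]


@dataclass(frozen=True)
class NetworkWidths:
    """Configurable channel widths of the encoder head and decoder."""

    aspp_channels: int = 256
    aspp_rates: tuple = (6, 12, 18)
    low_channels: int = 48
    refine_channels: int = 256
    se_reduction: int = 16

    def to_dict(self) -> dict:
        return {"aspp_channels": self.aspp_channels,
                "aspp_rates": list(self.aspp_rates),
                "low_channels": self.low_channels,
                "refine_channels": self.refine_channels,
                "se_reduction": self.se_reduction}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkWidths":
        d = dict(d)
        d["aspp_rates"] = tuple(d["aspp_rates"])
        return cls(**d)


#: Narrow profile for CPU-scale experiments: same topology, fewer channels.
DESK_WIDTHS = NetworkWidths(aspp_channels=96, low_channels=24,
                            refine_channels=64, se_reduction=8)


class SegmentationNetwork(nn.Module):
    """End-to-end per-pixel classifier over NHWC uint8/float images."""

    def __init__(self, variant: ModelVariant, backbone: MobileNetV2Backbone,
                 aspp: ASPP, decoder, widths: NetworkWidths):
        super().__init__()
        self.variant = variant
        self.widths = widths
        self.backbone = backbone
        self.aspp = aspp
        self.decoder = decoder

    @staticmethod
    def preprocess(images: np.ndarray) -> np.ndarray:
        """uint8 or float RGB batch → standardized float32 in [-1, 1]."""
        x = np.asarray(images)
        if x.ndim == 3:
            x = x[None]
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        else:
            x = x.astype(np.float32)
        return (x - 0.5) / 0.5

    def forward(self, images) -> nn.Tensor:
        if isinstance(images, nn.Tensor):
            x = images
        else:
            x = nn.Tensor(self.preprocess(images))
        taps = self.backbone(x)
        deep = taps[self.backbone.config.output_stride]
        encoded = self.aspp(deep)
        return self.decoder(encoded, taps)

    def predict(self, images, batch_size: int = 4) -> np.ndarray:
        """Per-pixel argmax class masks for a batch of images (eval mode)."""
        was_training = self.training
        self.eval()
        x = np.asarray(images)
        single = x.ndim == 3
        if single:
            x = x[None]
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size])
            out.append(np.argmax(logits.data, axis=-1).astype(np.uint8))
        if was_training:
            self.train()
        masks = np.concatenate(out, axis=0)
        return masks[0] if single else masks


def build_model(variant: ModelVariant,
                backbone_config: Optional[BackboneConfig] = None,
                widths: Optional[NetworkWidths] = None,
                seed: Optional[int] = None) -> SegmentationNetwork:
    """Construct a segmentation network for a variant with seeded init."""
    widths = widths or NetworkWidths()
    rng = np.random.default_rng(seed)
    backbone = MobileNetV2Backbone(backbone_config, rng=rng)
    aspp = ASPP(backbone.out_channels, widths.aspp_channels,
                rates=widths.aspp_rates, rng=rng)
    decoder = build_decoder(variant, widths.aspp_channels,
                            backbone.tapped_channels(),
                            low_channels=widths.low_channels,
                            refine_channels=widths.refine_channels,
                            se_reduction=widths.se_reduction, rng=rng)
    return SegmentationNetwork(variant, backbone, aspp, decoder, widths)


def save_checkpoint(model: SegmentationNetwork, path) -> None:
    """Serialize weights plus the full configuration header (.npz)."""
    header = json.dumps({
        "variant": model.variant.to_dict(),
        "backbone": model.backbone.config.to_dict(),
        "widths": model.widths.to_dict(),
    })
    state = model.state_dict()
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **{f"w/{k}": v for k, v in state.items()})


def load_checkpoint(path) -> SegmentationNetwork:
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"].tobytes()).decode())
        state = {k[2:]: z[k] for k in z.files if k.startswith("w/")}
    model = build_model(ModelVariant.from_dict(header["variant"]),
                        BackboneConfig.from_dict(header["backbone"]),
                        NetworkWidths.from_dict(header["widths"]))
    model.load_state_dict(state)
    return model
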