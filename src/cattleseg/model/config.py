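"""Architecture configuration types.

The backbone is the first four down-sampling blocks of MobileNetV2 with
the two deepest stage groups held at stride 1 (dilated where the nominal
network would stride), so the deepest feature map sits at 1/16 of the
input resolution (output stride 16) instead of 1/32.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import List, Tuple

from ..exceptions import ConfigurationError

__all__ = ["StageSpec", "BackboneConfig", "SEBlockSpec", "ModelVariant",
           "DEFAULT_STAGES", "NOMINAL_STAGES"]


@dataclass(frozen=True)
class StageSpec:
    """One group of repeated inverted-residual bottleneck blocks.

    ``expansion_t`` is the bottleneck expansion factor, ``out_channels_c``
    the output width, ``repeats_n`` the number of blocks, ``stride_s`` the
    stride of the first block, and ``dilation_rate`` the atrous rate of
    the depthwise convolutions.
    """

    expansion_t: int
    out_channels_c: int
    repeats_n: int
    stride_s: int
    dilation_rate: int = 1

    def __post_init__(self):
        if self.expansion_t < 1 or self.out_channels_c < 1 or self.repeats_n < 1:
            raise ConfigurationError("StageSpec fields must be positive")
        if self.stride_s not in (1, 2):
            raise ConfigurationError(f"stride_s must be 1 or 2, got {self.stride_s}")
        if self.dilation_rate < 1:
            raise ConfigurationError("dilation_rate must be positive")
        if self.stride_s == 2 and self.dilation_rate != 1:
            raise ConfigurationError(
                "a stage cannot combine stride 2 with dilation > 1")


#: Default stage table: (t, c, n, s, rate) per stage group. The last two
#: nominally striding groups run at stride 1, the final one dilated, so the
#: cumulative down-sampling factor stays at 16.
DEFAULT_STAGES: Tuple[StageSpec, ...] = (
    StageSpec(1, 16, 1, 1, 1),
    StageSpec(6, 24, 2, 2, 1),
    StageSpec(6, 32, 3, 2, 1),
    StageSpec(6, 64, 4, 2, 1),
    StageSpec(6, 96, 3, 1, 1),
    StageSpec(6, 160, 3, 1, 1),
    StageSpec(6, 320, 1, 1, 2),
)

#: Nominal MobileNetV2 strides (classification network): the c=160 group
#: strides, giving a 1/32 deepest map. Used to demonstrate the output-stride
#: difference, not as a segmentation default.
NOMINAL_STAGES: Tuple[StageSpec, ...] = (
    StageSpec(1, 16, 1, 1, 1),
    StageSpec(6, 24, 2, 2, 1),
    StageSpec(6, 32, 3, 2, 1),
    StageSpec(6, 64, 4, 2, 1),
    StageSpec(6, 96, 3, 1, 1),
    StageSpec(6, 160, 3, 2, 1),
    StageSpec(6, 320, 1, 1, 1),
)


@dataclass(frozen=True)
class BackboneConfig:
    """Stem + stage table + which down-sampling factors are tapped."""

    stem_channels: int = 32
    stem_stride: int = 2
    stages: Tuple[StageSpec, ...] = DEFAULT_STAGES
    tap_levels: Tuple[int, ...] = (2, 4, 8)

    @property
    def output_stride(self) -> int:
        s = self.stem_stride
        for st in self.stages:
            s *= st.stride_s
        return s

    @property
    def out_channels(self) -> int:
        return self.stages[-1].out_channels_c

    def to_dict(self) -> dict:
        return {"stem_channels": self.stem_channels,
                "stem_stride": self.stem_stride,
                "stages": [asdict(s) for s in self.stages],
                "tap_levels": list(self.tap_levels)}

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        return cls(stem_channels=d["stem_channels"], stem_stride=d["stem_stride"],
                   stages=tuple(StageSpec(**s) for s in d["stages"]),
                   tap_levels=tuple(d["tap_levels"]))


@dataclass(frozen=True)
class SEBlockSpec:
    """Squeeze-and-excitation block: channel count and FC bottleneck ratio."""

    channels: int
    reduction: int = 16

    def __post_init__(self):
        if self.channels < 1 or self.reduction < 1:
            raise ConfigurationError("SEBlockSpec fields must be positive")

    @property
    def hidden(self) -> int:
        return max(self.channels // self.reduction, 1)


@dataclass(frozen=True)
class ModelVariant:
    """Which decoder style and whether SE attention is used.

    The ablation grid: ``(layerwise, use_se=True)`` is the improved model
    (Imp); ``(layerwise, False)`` adds only the layer-by-layer decoder
    (M2-U); ``(simple, False)`` is the plain MobileNetV2-backbone model
    (M2) with the original single-fusion, two-4×-up-sampling decoder.
    """

    decoder_style: str = "layerwise"
    use_se: bool = True
    num_classes: int = 3

    _NAMES = {"imp": ("layerwise", True), "m2u": ("layerwise", False),
              "m2": ("simple", False)}

    def __post_init__(self):
        if self.decoder_style not in ("simple", "layerwise"):
            raise ConfigurationError(
                f"decoder_style must be 'simple' or 'layerwise', got {self.decoder_style!r}")
        if self.num_classes < 1:
            raise ConfigurationError("num_classes must be positive")
        if self.decoder_style == "simple" and self.use_se:
            raise ConfigurationError("SE attention is only defined for the layerwise decoder")

    @classmethod
    def from_name(cls, name: str, num_classes: int = 3) -> "ModelVariant":
        key = name.lower().replace("-", "").replace("_", "")
        if key not in cls._NAMES:
            raise ConfigurationError(f"unknown variant {name!r}; choose from imp, m2u, m2")
        style, se = cls._NAMES[key]
        return cls(decoder_style=style, use_se=se, num_classes=num_classes)

    @property
    def name(self) -> str:
        for k, v in self._NAMES.items():
            if v == (self.decoder_style, self.use_se):
                return k
        return f"{self.decoder_style}{'+se' if self.use_se else ''}"

    def to_dict(self) -> dict:
        return {"decoder_style": self.decoder_style, "use_se": self.use_se,
                "num_classes": self.num_classes}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelVariant":
        return cls(**d)
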