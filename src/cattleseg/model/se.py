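"""Squeeze-and-excitation channel attention.

Squeeze: global average pool to a 1×1×C descriptor. Excitation: two fully
connected layers — a reduction with hard-swish and an expansion with
hard-sigmoid — yielding one weight in [0, 1] per channel. Scale: the input
map is multiplied channel-wise by those weights.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .. import nn
from ..exceptions import ConfigurationError
from .config import SEBlockSpec

__all__ = ["SEBlock"]


class SEBlock(nn.Module):
    def __init__(self, spec: SEBlockSpec, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        self.fc1 = nn.Linear(spec.channels, spec.hidden, rng=rng)
        self.fc2 = nn.Linear(spec.hidden, spec.channels, rng=rng)

    def excitation_weights(self, x: nn.Tensor) -> nn.Tensor:
        """Per-channel weights in [0, 1] for an NHWC input, shape (N,1,1,C)."""
        n, h, w, c = x.data.shape
        if c != self.spec.channels:
            raise ConfigurationError(
                f"SE block built for {self.spec.channels} channels, input has {c}")
        s = nn.functional.global_avg_pool(x)                   # (N,1,1,C)
        s = nn.functional.reshape(s, (n, c))
        s = nn.functional.hswish(self.fc1(s))
        s = nn.functional.hsigmoid(self.fc2(s))
        return nn.functional.reshape(s, (n, 1, 1, c))

    def forward(self, x):
        return nn.functional.mul(x, self.excitation_weights(x))

    def pin_excitation(self, value: float) -> None:
        """Force the excitation output to a constant.

        The hard-sigmoid saturates at 0 for pre-activations ≤ −3 and at 1
        for ≥ +3, so zeroing the second FC weight and setting its bias to
        ±3 pins every channel weight exactly; ``value=1`` makes the block
        an identity, ``value=0`` zeroes its output.
        """
        if value not in (0.0, 1.0):
            raise ConfigurationError("excitation can only be pinned to 0 or 1")
        self.fc2.weight.data[...] = 0.0
        self.fc2.bias.data[...] = 3.0 if value == 1.0 else -3.0
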