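"""Atrous Spatial Pyramid Pooling encoder head.

Parallel branches over the deepest backbone map — a 1×1 convolution, one
3×3 atrous convolution per rate, and a global-average-pooling image
branch — concatenated and projected to the output width. Spatial size is
preserved. Rates (6, 12, 18) are the customary choice at output stride 16.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .. import nn
from ..exceptions import ConfigurationError

__all__ = ["ASPP"]


def _conv_bn_relu(cin, cout, k, dilation, rng):
    return nn.Sequential(nn.Conv2d(cin, cout, k, dilation=dilation, rng=rng),
                         nn.BatchNorm2d(cout), nn.ReLU())


class ASPP(nn.Module):
    def __init__(self, in_channels: int, out_channels: int = 256,
                 rates: Sequence[int] = (6, 12, 18),
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        if not rates or any(r < 1 for r in rates):
            raise ConfigurationError("ASPP rates must be a non-empty list of positive ints")
        rng = rng or np.random.default_rng()
        self.rates = tuple(rates)
        self.out_channels = out_channels
        self.branch_1x1 = _conv_bn_relu(in_channels, out_channels, 1, 1, rng)
        for i, r in enumerate(self.rates):
            setattr(self, f"branch_rate{i}", _conv_bn_relu(in_channels, out_channels, 3, r, rng))
        self.branch_pool = _conv_bn_relu(in_channels, out_channels, 1, 1, rng)
        n_branches = 2 + len(self.rates)
        self.project = _conv_bn_relu(n_branches * out_channels, out_channels, 1, 1, rng)

    @property
    def n_branches(self) -> int:
        return 2 + len(self.rates)

    def forward(self, x):
        n, h, w, c = x.data.shape
        outs = [self.branch_1x1(x)]
        for i in range(len(self.rates)):
            outs.append(getattr(self, f"branch_rate{i}")(x))
        pooled = self.branch_pool(nn.functional.global_avg_pool(x))   # (N,1,1,C')
        # broadcast the image-level feature back over the spatial grid
        zeros = nn.Tensor(np.zeros((n, h, w, pooled.data.shape[-1]),
                                   dtype=pooled.data.dtype))
        outs.append(nn.functional.add(pooled, zeros))
        return self.project(nn.functional.concat(outs, axis=-1))
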