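"""Layer/module system: parameter containers with train/eval state.

Modules register their parameters (learnable tensors) and buffers
(non-learnable state such as batch-norm running statistics) so that
optimisers, checkpointing and weight sharing can address them by
dotted name, in the style familiar from mainstream deep-learning APIs.
"""

from __future__ import annotations

from typing import Dict, Iterator, Optional, Tuple

import numpy as np

from . import functional as F
from .tensor import Tensor

DEFAULT_DTYPE = np.float32

__all__ = [
    "Parameter", "Module", "Sequential",
    "Conv2d", "DepthwiseConv2d", "Linear", "BatchNorm2d",
    "ReLU", "ReLU6", "HSwish", "HSigmoid", "Identity",
]


class Parameter(Tensor):
    """A tensor that is learnable (``requires_grad=True``)."""

    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data, dtype=DEFAULT_DTYPE), requires_grad=True)


class Module:
    """Base class: tracks sub-modules, parameters and buffers by attribute."""

    def __init__(self):
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[Tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for mod_name, mod in self.named_modules(prefix):
            for p_name, p in mod._params.items():
                yield (f"{mod_name}.{p_name}" if mod_name else p_name), p

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for mod_name, mod in self.named_modules(prefix):
            for b_name in mod._buffers:
                yield (f"{mod_name}.{b_name}" if mod_name else b_name), mod._buffers[b_name]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- mode ----------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for _, mod in self.named_modules():
            object.__setattr__(mod, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- serialisation -------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state[name] = np.array(b, copy=True)
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict((n, (m, bn)) for n, (m, bn) in
                    ((name, (mod, b_name))
                     for mod_name, mod in self.named_modules()
                     for b_name in mod._buffers
                     for name in [f"{mod_name}.{b_name}" if mod_name else b_name]))
        for name, value in state.items():
            if name in own:
                if own[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{own[name].data.shape} vs {value.shape}")
                own[name].data = np.asarray(value, dtype=DEFAULT_DTYPE).copy()
            elif name in bufs:
                mod, b_name = bufs[name]
                mod._buffers[b_name][...] = value
            else:
                raise KeyError(f"unexpected entry in state dict: {name}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._order = [str(i) for i in range(len(mods))]

    def __iter__(self):
        return iter(self._modules[k] for k in self._order)

    def __len__(self):
        return len(self._order)

    def forward(self, x):
        for k in self._order:
            x = self._modules[k](x)
        return x


# -- concrete layers ---------------------------------------------------------

class Conv2d(Module):
    """Dense 2-D convolution; Kaiming-normal (fan-out) initialisation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, dilation: int = 1, bias: bool = False,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dilation = dilation
        fan_out = kernel_size * kernel_size * out_channels
        std = float(np.sqrt(2.0 / fan_out))
        self.weight = Parameter(rng.normal(0.0, std,
                                           (kernel_size, kernel_size, in_channels, out_channels)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias,
                        stride=self.stride, dilation=self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel_size: int = 3, stride: int = 1,
                 dilation: int = 1, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dilation = dilation
        fan_out = kernel_size * kernel_size
        std = float(np.sqrt(2.0 / fan_out))
        self.weight = Parameter(rng.normal(0.0, std, (kernel_size, kernel_size, channels)))

    def forward(self, x):
        return F.depthwise_conv2d(x, self.weight, stride=self.stride,
                                  dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = float(np.sqrt(2.0 / in_features))
        self.weight = Parameter(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics.

    ``eps`` and ``momentum`` follow common framework defaults and are
    recorded on the instance so checkpoints are self-describing.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float64))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float64))

    def forward(self, x):
        return F.batch_norm(x, self.gamma, self.beta,
                            self.running_mean, self.running_var,
                            training=self.training,
                            momentum=self.momentum, eps=self.eps)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class ReLU6(Module):
    def forward(self, x):
        return F.relu6(x)


class HSwish(Module):
    def forward(self, x):
        return F.hswish(x)


class HSigmoid(Module):
    def forward(self, x):
        return F.hsigmoid(x)


class Identity(Module):
    def forward(self, x):
        return x
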