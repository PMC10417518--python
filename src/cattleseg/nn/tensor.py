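"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps one
``numpy.ndarray`` and remembers the tensors it was computed from together
with a closure that propagates the output gradient back to them.
``Tensor.backward()`` runs the closures in reverse topological order.

Activations are stored in whatever dtype the inputs carry (float32 in
normal use, float64 in finite-difference gradient checks).
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np

__all__ = ["Tensor", "as_tensor"]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation.

    Parameters
    ----------
    data:
        Array value of this node.
    requires_grad:
        Whether gradients should be accumulated into ``self.grad``.
    parents:
        Tensors this node was computed from (graph edges).
    backward_fn:
        Closure called with the output gradient; it must add the
        appropriate contributions to each parent's ``grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Iterable["Tensor"] = (),
        backward_fn: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: Optional[np.ndarray] = None
        self._parents = tuple(parents)
        self._backward_fn = backward_fn

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- gradient accumulation ----------------------------------------------
    def accumulate_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this node through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order by depth-first search
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.accumulate_grad(grad)
        for node in reversed(order):
            if node._backward_fn is not None and node.grad is not None:
                node._backward_fn(node.grad)
                # free intermediate gradients to bound peak memory
                if not node.requires_grad:
                    node.grad = None

    # -- ergonomic operators (thin wrappers over functional ops) -------------
    def __add__(self, other):
        from . import functional as F

        return F.add(self, as_tensor(other, self.dtype))

    def __mul__(self, other):
        from . import functional as F

        return F.mul(self, as_tensor(other, self.dtype))

    def sum(self):
        from . import functional as F

        return F.sum_all(self)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=dtype)
    return Tensor(arr)
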