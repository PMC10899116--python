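"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient
buffer and a closure that propagates gradients to its parents.  The graph is
built eagerly by the arithmetic helpers in :mod:`anorak.nn.functional`;
``Tensor.backward`` runs a topological sweep.  Only the operations needed by
the segmentation network are provided — this is a training core, not a
general framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]

#: float32 keeps training fast; tests may switch to float64 for finite
#: difference gradient checks.
DTYPE = np.float32


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of a scalar (or supplied seed) into leaves."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=DTYPE)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for 60-epoch nets
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

        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # interior activations: free the buffer once consumed
                node.grad = None

    def accumulate(self, grad):
        if self.grad is None:
            self.grad = np.asarray(grad, dtype=DTYPE).copy()
        else:
            self.grad += grad

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- numpy views ---------------------------------------------------
    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- operators (delegated to functional) ---------------------------
    def __add__(self, other):
        from . import functional as F

        return F.add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        from . import functional as F

        return F.mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        from . import functional as F

        return F.add(self, F.mul(other, -1.0))

    def __truediv__(self, other):
        from . import functional as F

        return F.mul(self, F.power(other, -1.0))

    def __pow__(self, p):
        from . import functional as F

        return F.power(self, p)

    def __matmul__(self, other):
        from . import functional as F

        return F.matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        from . import functional as F

        return F.sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        from . import functional as F

        return F.mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        from . import functional as F

        return F.reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        from . import functional as F

        return F.transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
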