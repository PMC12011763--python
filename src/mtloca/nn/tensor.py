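"""Minimal reverse-mode autodiff over NumPy arrays.

Small by design: exactly the operations the segmentation/classification
network needs, each with an analytically derived backward pass that is
verified against central finite differences in the test suite.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    """An array node in the autodiff graph.

    ``data`` is a plain ndarray; ``grad`` is populated by :meth:`backward`.
    Graph edges are stored as parent tensors plus a closure that pushes the
    gradient of this node into its parents.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward
        self._grad_borrowed = False

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery ----------------------------------------------
    def _accumulate(self, g):
        # First contribution borrows the buffer (never mutated in place while
        # borrowed); later contributions allocate the sum once.
        if self.grad is None:
            self.grad = g
            self._grad_borrowed = True
        elif self._grad_borrowed:
            self.grad = self.grad + g
            self._grad_borrowed = False
        else:
            self.grad += g

    def backward(self, grad=None):
        """Reverse-mode sweep from this node.

        ``grad`` defaults to 1 and therefore requires a scalar output.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None
        self._grad_borrowed = False

    # -- operator sugar (thin wrappers over mtloca.nn.functional) ------
    def __add__(self, other):
        from . import functional as F
        return F.add(self, other)

    def __mul__(self, other):
        from . import functional as F
        return F.mul(self, other)

    __radd__ = __add__
    __rmul__ = __mul__

    def __neg__(self):
        from . import functional as F
        return F.mul(self, -1.0)

    def __sub__(self, other):
        from . import functional as F
        return F.add(self, F.mul(other if isinstance(other, Tensor) else Tensor(other), -1.0))

    def reshape(self, *shape):
        from . import functional as F
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return F.reshape(self, shape)

    def transpose(self, *axes):
        from . import functional as F
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return F.transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        from . import functional as F
        return F.sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        from . import functional as F
        return F.mean(self, axis=axis, keepdims=keepdims)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
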