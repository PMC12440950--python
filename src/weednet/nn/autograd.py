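"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the style of the classic define-by-run
frameworks: each operation builds a :class:`Tensor` holding the forward
value and a closure that routes the upstream gradient to its parents.
``backward()`` walks the graph in reverse topological order.

Only float32 is used for learnable state; gradients accumulate in the
same dtype as the data.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Optional, Sequence, Tuple, Union

import numpy as np

Arrayish = Union[np.ndarray, float, int, "Tensor"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


def _as_array(x, dtype=np.float32) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(dtype, copy=False) if x.dtype != dtype else x
    return np.asarray(x, dtype=dtype)


class Tensor:
    """An n-d array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: Arrayish,
        requires_grad: bool = False,
        _parents: Tuple["Tensor", ...] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        if isinstance(data, Tensor):
            data = data.data
        self.data = _as_array(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def result(
        data: np.ndarray,
        parents: Sequence["Tensor"],
        backward: Callable[[np.ndarray], None],
    ) -> "Tensor":
        """Build the output node of an op, respecting the global grad switch."""
        needs = _grad_enabled and any(p.requires_grad for p in parents)
        if not needs:
            return Tensor(data)
        return Tensor(data, requires_grad=True, _parents=tuple(parents), _backward=backward)

    def accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.asarray(g, dtype=self.data.dtype).copy()
        else:
            self.grad += g

    # -- properties -----------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.size != 1:
                raise RuntimeError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads eagerly except on leaves
                if node._parents:
                    node.grad = None
                    node._backward = None
                    node._parents = ()

    # -- operators (implemented in functional.py, bound late) -----------------
    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor registered by modules as learnable state."""

    __slots__ = ()

    def __init__(self, data: Arrayish):
        super().__init__(data, requires_grad=True)


def as_tensor(x: Arrayish) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)
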