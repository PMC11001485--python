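"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package trains graph neural networks with plain NumPy; this module
provides the small set of differentiable primitives the encoders and
losses need: broadcasting arithmetic, matmul, gather/scatter (for message
passing and pooling), row normalisation and log-softmax.

Design notes
------------
* ``Tensor`` wraps a float64 ``ndarray``.  Gradients accumulate into
  ``Tensor.grad`` only for leaves created with ``requires_grad=True``.
* ``backward(root)`` may be called on several scalar roots of the same
  graph; each call uses a private gradient table, so snapshotting the
  gradient of one loss term before back-propagating the total is cheap.
* All primitives have analytically exact backward rules; the test-suite
  checks them against central finite differences.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "backward"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional autodiff tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward_fn: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float64))

    @staticmethod
    def _node(data: np.ndarray, parents: tuple["Tensor", ...], backward_fn) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = parents
            out._backward_fn = backward_fn
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        a, b = self, other

        def bwd(g):
            return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

        return Tensor._node(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self
        return Tensor._node(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        a, b = self, other

        def bwd(g):
            return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

        return Tensor._node(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        a, b = self, other

        def bwd(g):
            return (
                _unbroadcast(g / b.data, a.shape),
                _unbroadcast(-g * a.data / (b.data**2), b.shape),
            )

        return Tensor._node(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        a = self
        e = float(exponent)

        def bwd(g):
            return (g * e * np.power(a.data, e - 1.0),)

        return Tensor._node(np.power(a.data, e), (a,), bwd)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        a, b = self, other

        def bwd(g):
            return g @ b.data.T, a.data.T @ g

        return Tensor._node(a.data @ b.data, (a, b), bwd)

    @property
    def T(self) -> "Tensor":
        a = self
        return Tensor._node(a.data.T, (a,), lambda g: (g.T,))

    # ---------------------------------------------------------- element-wise
    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0
        return Tensor._node(a.data * mask, (a,), lambda g: (g * mask,))

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)
        return Tensor._node(out_data, (a,), lambda g: (g * out_data,))

    def log(self) -> "Tensor":
        a = self
        return Tensor._node(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self) -> "Tensor":
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._node(out_data, (a,), lambda g: (g / (2.0 * out_data),))

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.shape).copy(),)

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        count = a.data.size if axis is None else a.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # ------------------------------------------------------- gather / scatter
    def take_rows(self, index: np.ndarray) -> "Tensor":
        """Row gather ``out[i] = self[index[i]]`` (embedding lookup)."""
        a = self
        index = np.asarray(index, dtype=np.int64)

        def bwd(g):
            out = np.zeros_like(a.data)
            np.add.at(out, index, g)
            return (out,)

        return Tensor._node(a.data[index], (a,), bwd)

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int) -> "Tensor":
        """Scatter-add rows into ``num_segments`` buckets (message aggregation)."""
        a = self
        segment_ids = np.asarray(segment_ids, dtype=np.int64)
        out_data = np.zeros((num_segments,) + a.data.shape[1:], dtype=np.float64)
        np.add.at(out_data, segment_ids, a.data)

        def bwd(g):
            return (g[segment_ids],)

        return Tensor._node(out_data, (a,), bwd)

    def segment_mean(self, segment_ids: np.ndarray, num_segments: int) -> "Tensor":
        counts = np.bincount(np.asarray(segment_ids), minlength=num_segments).astype(np.float64)
        counts = np.maximum(counts, 1.0)[:, None]
        return self.segment_sum(segment_ids, num_segments) / Tensor(counts)

    def segment_max(self, segment_ids: np.ndarray, num_segments: int) -> "Tensor":
        """Per-segment max with subgradient routed to the arg-max rows."""
        a = self
        segment_ids = np.asarray(segment_ids, dtype=np.int64)
        out_data = np.full((num_segments,) + a.data.shape[1:], -np.inf)
        np.maximum.at(out_data, segment_ids, a.data)
        is_max = a.data == out_data[segment_ids]

        def bwd(g):
            return (g[segment_ids] * is_max,)

        return Tensor._node(out_data, (a,), bwd)

    def batchnorm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Fused train-mode batch normalisation over rows (2-D input).

        Single primitive with an analytic backward; equivalent to the
        op-by-op composition but avoids a chain of large temporaries.
        """
        a = self
        n = a.data.shape[0]
        mean = a.data.mean(axis=0)
        centered = a.data - mean
        var = np.einsum("ij,ij->j", centered, centered) / n
        inv_std = 1.0 / np.sqrt(var + eps)
        x_hat = centered * inv_std

        def bwd(g):
            g_gamma = np.einsum("ij,ij->j", g, x_hat)
            g_beta = g.sum(axis=0)
            gx_hat = g * gamma.data
            g_input = (
                gx_hat - gx_hat.mean(axis=0) - x_hat * (np.einsum("ij,ij->j", gx_hat, x_hat) / n)
            ) * inv_std
            return g_input, g_gamma, g_beta

        out = Tensor._node(x_hat * gamma.data + beta.data, (a, gamma, beta), bwd)
        return out

    # ------------------------------------------------------------- composites
    def log_softmax(self) -> "Tensor":
        """Numerically stable row-wise log-softmax (2-D input)."""
        a = self
        shifted = a.data - a.data.max(axis=1, keepdims=True)
        log_z = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        out_data = shifted - log_z
        softmax = np.exp(out_data)

        def bwd(g):
            return (g - softmax * g.sum(axis=1, keepdims=True),)

        return Tensor._node(out_data, (a,), bwd)

    def l2_normalize_rows(self) -> "Tensor":
        """Rows scaled to unit L2 norm; all-zero rows stay zero."""
        a = self
        norms = np.linalg.norm(a.data, axis=1, keepdims=True)
        safe = np.where(norms == 0.0, 1.0, norms)
        out_data = a.data / safe

        def bwd(g):
            dot = (g * out_data).sum(axis=1, keepdims=True)
            return ((g - out_data * dot) / safe,)

        return Tensor._node(out_data, (a,), bwd)


def backward(root: Tensor) -> None:
    """Back-propagate from a scalar ``root``, accumulating into leaf ``.grad``.

    The graph is left intact, so a second call on another root (e.g. the
    total loss after snapshotting one term's gradient) reuses it.
    """
    if root.data.size != 1:
        raise ValueError("backward() expects a scalar root")

    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent in node._parents:
            if id(parent) not in seen:
                stack.append((parent, False))

    grads: dict[int, np.ndarray] = {id(root): np.ones_like(root.data)}
    for node in reversed(topo):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if node.requires_grad:
            node.grad = g.copy() if node.grad is None else node.grad + g
        if node._backward_fn is None:
            continue
        parent_grads = node._backward_fn(g)
        for parent, pg in zip(node._parents, parent_grads):
            if pg is None or not (parent.requires_grad or parent._parents):
                continue
            if id(parent) in grads:
                grads[id(parent)] = grads[id(parent)] + pg
            else:
                grads[id(parent)] = pg
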