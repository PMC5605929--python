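"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based engine with exactly the operator set the tagger's encoder
needs: broadcast arithmetic, matmul, sigmoid/tanh, concatenation,
slicing, embedding gather, max-pooling, dropout, and a fused softmax
cross-entropy.  Gradients propagate through a topologically sorted tape;
broadcasting is undone by summing over broadcast axes.

This is deliberately small: no graph optimization, no higher-order
derivatives, float64 throughout (the workloads here are tiny and
benefit more from numerical headroom than from speed tricks).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["Tensor", "concat", "stack", "sigmoid", "tanh", "relu",
           "embedding_lookup", "max_pool_axis", "dropout",
           "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node on the autodiff tape wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def _grad_buffer(self) -> np.ndarray:
        """Gradient array for in-place accumulation by backward closures."""
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        return self.grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS: tapes from long RNNs exceed recursion depth
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node.parents
                         if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    def _binary(self, other, fwd, bwd_a, bwd_b) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(fwd(self.data, other.data), parents=(self, other))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(bwd_a(g), self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(bwd_b(g), other.shape))

        out._backward = backward
        return out

    def __add__(self, other):
        return self._binary(other, np.add, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract, lambda g: g, lambda g: -g)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other_t = other if isinstance(other, Tensor) else Tensor(other)
        return self._binary(
            other_t, np.multiply,
            lambda g: g * other_t.data, lambda g: g * self.data,
        )

    __rmul__ = __mul__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if other.data.ndim == 2 and g.ndim > 2:
                    # shared weight applied over leading batch axes: one
                    # flattened BLAS call instead of a batched einsum
                    d = self.data.reshape(-1, self.data.shape[-1])
                    gb = d.T @ g.reshape(-1, g.shape[-1])
                    other._accumulate(gb)
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    __matmul__ = matmul

    def sum(self, axis=None) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis), parents=(self,))

        def backward(g: np.ndarray) -> None:
            if axis is None:
                self._accumulate(np.full_like(self.data, float(g)))
            else:
                self._accumulate(np.broadcast_to(
                    np.expand_dims(g, axis), self.shape).copy())

        out._backward = backward
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def __getitem__(self, idx) -> "Tensor":
        # supported index forms never select the same element twice
        # (ints + slices), so in-place += is a valid scatter-add
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g: np.ndarray) -> None:
            self._grad_buffer()[idx] += g

        out._backward = backward
        return out


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x._accumulate(g * s * (1.0 - s))
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, parents=(x,))
    out._backward = lambda g: x._accumulate(g * (1.0 - t * t))
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))

    def backward(g: np.ndarray) -> None:
        pieces = np.moveaxis(g, axis, 0)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = backward
    return out


def embedding_lookup(table: Tensor, indices: np.ndarray) -> Tensor:
    """Gather rows of ``table`` at integer ``indices`` (any shape)."""
    indices = np.asarray(indices, dtype=int)
    out = Tensor(table.data[indices], parents=(table,))

    def backward(g: np.ndarray) -> None:
        if table.requires_grad:
            np.add.at(table._grad_buffer(), indices.ravel(),
                      g.reshape(-1, g.shape[-1]))

    out._backward = backward
    return out


def max_pool_axis(x: Tensor, axis: int, mask: np.ndarray | None = None) -> Tensor:
    """Max over one axis; ``mask`` (broadcastable, bool) excludes positions.

    Positions excluded by the mask are treated as ``-inf``; an all-masked
    slice pools to 0 with zero gradient.
    """
    data = x.data
    if mask is not None:
        data = np.where(mask, data, -np.inf)
    pooled = data.max(axis=axis)
    empty = ~np.isfinite(pooled)
    pooled = np.where(empty, 0.0, pooled)
    argmax = data.argmax(axis=axis)
    out = Tensor(pooled, parents=(x,))

    def backward(g: np.ndarray) -> None:
        g_eff = np.where(empty, 0.0, g)
        idx = list(np.indices(pooled.shape))
        idx.insert(axis if axis >= 0 else x.data.ndim + axis, argmax)
        np.add.at(x._grad_buffer(), tuple(idx), g_eff)

    out._backward = backward
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = rng.random(x.shape) >= rate
    scale = keep / (1.0 - rate)
    out = Tensor(x.data * scale, parents=(x,))
    out._backward = lambda g: x._accumulate(g * scale)
    return out


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray,
                          weights: np.ndarray | None = None) -> Tensor:
    """Summed cross-entropy of integer ``targets`` under row softmax.

    ``logits`` is (..., K); ``weights`` (broadcastable to the leading
    shape) zeroes out padded positions.  The fused form is numerically
    stable and gives the textbook ``softmax - onehot`` gradient.
    """
    z = logits.data
    z_max = z.max(axis=-1, keepdims=True)
    ez = np.exp(z - z_max)
    probs = ez / ez.sum(axis=-1, keepdims=True)
    targets = np.asarray(targets, dtype=int)
    lead = z.shape[:-1]
    gather = np.take_along_axis(
        np.log(probs), targets.reshape(*lead, 1), axis=-1)[..., 0]
    w = np.ones(lead) if weights is None else np.broadcast_to(weights, lead)
    out = Tensor(-(gather * w).sum(), parents=(logits,))

    def backward(g: np.ndarray) -> None:
        onehot = np.zeros_like(z)
        np.put_along_axis(onehot, targets.reshape(*lead, 1), 1.0, axis=-1)
        logits._accumulate(float(g) * (probs - onehot) * w[..., None])

    out._backward = backward
    return out
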