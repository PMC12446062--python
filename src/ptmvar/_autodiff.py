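"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is a deliberately small tape-based engine — just the primitives the
convolutional/recurrent sequence classifiers in this package need: broadcast
arithmetic, matmul, the usual activations, reductions, shape ops, a 1-D
``same``-padded patch extractor for convolutions and a stride-2 max pool.
Gradients flow through an explicitly recorded DAG; ``backward`` runs a
topological sweep accumulating into ``.grad``.

Float32 throughout; broadcasting in binary ops is undone on the backward
pass by summing gradients back to each parent's shape.
"""

from __future__ import annotations

import numpy as np


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reverse numpy broadcasting: reduce grad back to `shape`."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    # -- graph mechanics ---------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs from unrolled RNNs get deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- operators ---------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_sum_to_shape(g, a.shape))
            if b.requires_grad:
                b._accumulate(_sum_to_shape(g, b.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_sum_to_shape(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_sum_to_shape(g * a.data, b.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __sub__(self, other):
        return self + (_as_tensor(other) * -1.0)

    def __rsub__(self, other):
        return _as_tensor(other) + (self * -1.0)

    def __neg__(self):
        return self * -1.0

    def matmul(self, other: "Tensor") -> "Tensor":
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.reshape(-1, a.shape[-1]).T @ g.reshape(-1, g.shape[-1]))

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    def __matmul__(self, other):
        return self.matmul(other)

    # -- activations -------------------------------------------------------

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g, a=self, o=out_data):
            a._accumulate(g * o * (1.0 - o))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bwd(g, a=self, o=out_data):
            a._accumulate(g * (1.0 - o * o))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g, a=self, m=mask):
            a._accumulate(g * m)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def elu(self, alpha: float = 1.0) -> "Tensor":
        neg = self.data <= 0
        expm1 = np.expm1(np.clip(self.data, -60, 0))
        out_data = np.where(neg, alpha * expm1, self.data)

        def bwd(g, a=self, n=neg, e=expm1):
            a._accumulate(g * np.where(n, alpha * (e + 1.0), 1.0))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g, a=self):
            a._accumulate(g / a.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def bwd(g, a=self, o=out_data):
            a._accumulate(g * 0.5 / o)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def reciprocal(self) -> "Tensor":
        out_data = 1.0 / self.data

        def bwd(g, a=self, o=out_data):
            a._accumulate(-g * o * o)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other.reciprocal()

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g, a=self):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).astype(np.float32))

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            scale = 1.0 / self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            scale = 1.0 / np.prod([self.shape[a] for a in axes])
        return self.sum(axis=axis, keepdims=keepdims) * float(scale)

    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def bwd(g, a=self):
            a._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def timestep(self, t: int) -> "Tensor":
        """Slice x[:, t, :] from a (B, L, C) tensor."""

        def bwd(g, a=self):
            full = np.zeros(a.shape, dtype=np.float32)
            full[:, t, :] = g
            a._accumulate(full)

        return Tensor(self.data[:, t, :], parents=(self,), backward=bwd)

    def concat(self, other: "Tensor", axis: int = -1) -> "Tensor":
        split = self.shape[axis]

        def bwd(g, a=self, b=other):
            ga, gb = np.split(g, [split], axis=axis)
            if a.requires_grad:
                a._accumulate(ga)
            if b.requires_grad:
                b._accumulate(gb)

        return Tensor(
            np.concatenate([self.data, other.data], axis=axis),
            parents=(self, other),
            backward=bwd,
        )


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def unfold_same(x: Tensor, kernel: int) -> Tensor:
    """Extract length-preserving 1-D patches: (B, L, C) -> (B, L, K*C).

    Zero padding of kernel//2 on both ends (``same`` convolution); a matmul
    of the result with a (K*C, F) weight implements the conv layer.
    """
    batch, length, channels = x.shape
    half = kernel // 2
    padded = np.pad(x.data, ((0, 0), (half, half), (0, 0)))
    idx = np.arange(length)[:, None] + np.arange(kernel)[None, :]  # (L, K)
    patches = padded[:, idx, :].reshape(batch, length, kernel * channels)

    def bwd(g, a=x):
        g4 = g.reshape(batch, length, kernel, channels)
        gpad = np.zeros((batch, length + 2 * half, channels), dtype=np.float32)
        np.add.at(gpad, (slice(None), idx, slice(None)), g4)
        a._accumulate(gpad[:, half : half + length, :])

    return Tensor(patches, parents=(x,), backward=bwd)


def max_pool1d(x: Tensor, pool: int = 2) -> Tensor:
    """Non-overlapping max pool along axis 1; trailing remainder dropped."""
    batch, length, channels = x.shape
    out_len = length // pool
    if out_len == 0:
        return x
    trimmed = x.data[:, : out_len * pool, :].reshape(batch, out_len, pool, channels)
    arg = trimmed.argmax(axis=2)
    out_data = np.take_along_axis(trimmed, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def bwd(g, a=x):
        full = np.zeros((batch, out_len, pool, channels), dtype=np.float32)
        np.put_along_axis(full, arg[:, :, None, :], g[:, :, None, :], axis=2)
        grad = np.zeros(a.shape, dtype=np.float32)
        grad[:, : out_len * pool, :] = full.reshape(batch, out_len * pool, channels)
        a._accumulate(grad)

    return Tensor(out_data, parents=(x,), backward=bwd)


def binary_cross_entropy(p: Tensor, targets: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean BCE between predicted probabilities and 0/1 targets."""
    y = np.asarray(targets, dtype=np.float32).reshape(p.shape)
    pc_data = np.clip(p.data, eps, 1.0 - eps)

    def bwd(g, a=p, pc=pc_data):
        inside = (pc > eps) & (pc < 1.0 - eps)
        a._accumulate(g * inside * (pc - y) / (pc * (1.0 - pc) * y.size))

    loss_data = -np.mean(y * np.log(pc_data) + (1.0 - y) * np.log(1.0 - pc_data))
    return Tensor(loss_data, parents=(p,), backward=bwd)
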