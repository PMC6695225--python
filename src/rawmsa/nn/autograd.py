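"""Compact reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the network layers need: broadcasting
arithmetic, matmul, pointwise nonlinearities, shape surgery (reshape,
transpose, slicing, concatenation), axis reductions (sum/mean/max),
integer table lookup (for embedding layers) and a fused
softmax/cross-entropy loss. Gradients flow through a tape built on the
fly; ``Tensor.backward()`` walks it in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "sparse_softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------

    @classmethod
    def _make(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- nonlinearities ---------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    # -- shape surgery ----------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[key] = g
                self._accumulate(full)

        return Tensor._make(self.data[key], (self,), backward)

    def pad_axis(self, axis: int, before: int, after: int):
        """Zero-pad along one axis."""
        widths = [(0, 0)] * self.data.ndim
        widths[axis] = (before, after)
        n = self.data.shape[axis]
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(before, before + n)
        sl = tuple(sl)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g[sl])

        return Tensor._make(np.pad(self.data, widths), (self,), backward)

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            count = self.data.size
        elif isinstance(axis, tuple):
            count = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            count = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int):
        out_data = self.data.max(axis=axis)
        argmax = self.data.argmax(axis=axis)

        def backward(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            idx = list(np.indices(out_data.shape))
            idx.insert(axis, argmax)
            full[tuple(idx)] = g
            self._accumulate(full)

        return Tensor._make(out_data, (self,), backward)

    # -- lookup -----------------------------------------------------------

    def take_rows(self, indices: np.ndarray):
        """Row lookup `self[indices]` for an integer index array.

        The gradient scatter-adds back into the looked-up rows, which is
        exactly the embedding-layer backward pass.
        """
        indices = np.asarray(indices)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, indices.ravel(), g.reshape(-1, self.data.shape[-1]))
                self._accumulate(full)

        return Tensor._make(self.data[indices], (self,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), backward)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain-numpy softmax for inference-time probabilities."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sparse_softmax_cross_entropy(
    logits: Tensor, targets: np.ndarray, mask: np.ndarray | None = None
) -> Tensor:
    """Mean cross-entropy between softmax(logits) and integer targets.

    `logits` has shape (..., C); `targets` the matching integer shape.
    Masked-out positions (mask == False) contribute nothing.
    """
    targets = np.asarray(targets)
    probs = softmax(logits.data, axis=-1)
    flat_p = probs.reshape(-1, probs.shape[-1])
    flat_t = targets.ravel()
    if mask is None:
        flat_m = np.ones(flat_t.shape, dtype=bool)
    else:
        flat_m = np.asarray(mask).ravel().astype(bool)
    n = max(int(flat_m.sum()), 1)
    picked = flat_p[np.arange(flat_t.size), flat_t]
    loss = -np.log(np.clip(picked[flat_m], 1e-12, None)).sum() / n

    def backward(g):
        if not logits.requires_grad:
            return
        grad = flat_p.copy()
        grad[np.arange(flat_t.size), flat_t] -= 1.0
        grad[~flat_m] = 0.0
        grad *= g / n
        logits._accumulate(grad.reshape(logits.data.shape))

    return Tensor._make(np.array(loss), (logits,), backward)
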