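"""Minimal reverse-mode automatic differentiation over numpy arrays.

Exactly the operations the geometric vector perceptron network needs:
broadcast add/mul, matrix products on the last axis, channel-wise linear
maps over stacked 3-vectors, safe Euclidean norms, concatenation, row
gather and segment-mean aggregation, elementwise nonlinearities, and
reductions. float64 throughout; gradients are accumulated by a reverse
topological sweep over the recorded tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather", "segment_mean", "stack_loss"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / scalar)

    def matmul(self, w: "Tensor") -> "Tensor":
        """x @ W on the last axis: (..., a) x (a, b) -> (..., b)."""
        w = self._wrap(w)
        out_data = self.data @ w.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ w.data.T)
            if w.requires_grad:
                x2 = self.data.reshape(-1, self.data.shape[-1])
                g2 = g.reshape(-1, g.shape[-1])
                w._accumulate(x2.T @ g2)

        return Tensor._make(out_data, (self, w), backward)

    def channel_matmul(self, w: "Tensor") -> "Tensor":
        """Linear map over the vector-channel axis of stacked 3-vectors:
        (..., v, 3) x (v, w) -> (..., w, 3)."""
        w = self._wrap(w)
        out_data = np.einsum("...vc,vw->...wc", self.data, w.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.einsum("...wc,vw->...vc", g, w.data))
            if w.requires_grad:
                x3 = self.data.reshape(-1, self.data.shape[-2], 3)
                g3 = g.reshape(-1, g.shape[-2], 3)
                w._accumulate(np.einsum("bvc,bwc->vw", x3, g3))

        return Tensor._make(out_data, (self, w), backward)

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def norm(self, eps: float = 1e-8) -> "Tensor":
        """Euclidean norm over the trailing 3-axis: (..., v, 3) -> (..., v).

        Softened as sqrt(sum + eps^2) so the gradient stays finite at the
        zero vector.
        """
        sq = np.sum(self.data**2, axis=-1)
        out_data = np.sqrt(sq + eps * eps)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g[..., None] * self.data / out_data[..., None])

        return Tensor._make(out_data, (self,), backward)

    # -- reductions & shaping ----------------------------------------------

    def sum(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, float(g)))

        return Tensor._make(self.data.sum(), (self,), backward)

    def mean(self) -> "Tensor":
        n = self.data.size

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, float(g) / n))

        return Tensor._make(self.data.mean(), (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def gather(x: Tensor, index: np.ndarray) -> Tensor:
    """Row gather along axis 0: out[e] = x[index[e]]."""
    index = np.asarray(index, dtype=int)
    out_data = x.data[index]

    def backward(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, index, g)
            x._accumulate(acc)

    return Tensor._make(out_data, (x,), backward)


def segment_mean(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Mean of rows of x grouped by segment id; empty segments give zero.

    Used for averaging incident-edge messages per node; division is by
    the actual segment size, not a fixed neighbor count.
    """
    segment_ids = np.asarray(segment_ids, dtype=int)
    counts = np.bincount(segment_ids, minlength=n_segments).astype(float)
    safe = np.maximum(counts, 1.0)
    out_data = np.zeros((n_segments,) + x.data.shape[1:])
    np.add.at(out_data, segment_ids, x.data)
    out_data /= safe.reshape((n_segments,) + (1,) * (x.data.ndim - 1))

    def backward(g):
        if x.requires_grad:
            scaled = g / safe.reshape((n_segments,) + (1,) * (g.ndim - 1))
            x._accumulate(scaled[segment_ids])

    return Tensor._make(out_data, (x,), backward)


def stack_loss(pred: Tensor, target: np.ndarray, weight: np.ndarray | None = None,
               eps: float = 1e-9) -> Tensor:
    """Binary cross-entropy with soft targets over a 1-D probability tensor."""
    t = Tensor(np.asarray(target, dtype=float))
    w = np.ones_like(t.data) if weight is None else np.asarray(weight, dtype=float)
    p = pred
    one_m = 1.0 - p
    # clip via the safe log argument
    term = t * (p + eps).log() + (1.0 - t) * (one_m + eps).log()
    weighted = term * Tensor(w)
    return -(weighted.sum() / max(float(w.sum()), eps))
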