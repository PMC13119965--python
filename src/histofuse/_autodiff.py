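"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A tape-based ``Tensor`` supporting exactly the operations the package's
networks need: broadcasting arithmetic, matmul, elementwise nonlinearities,
axis reductions, reshaping, row/column gathers (which also back convolution
via im2col), segment sums (which back neighborhood attention softmax), and
2x2 max pooling. Gradients are accumulated by topological traversal.

float64 throughout (loss closed forms are exact to numerical precision);
gradients are checked against central differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "DTYPE"]

DTYPE = np.float64


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * DTYPE(-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        return self._make(self.data**e, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise ----------------------------------------------------------
    def exp(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g * out.data)

        return self._make(np.exp(self.data), (self,), backward)

    def log(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g * DTYPE(0.5) / out.data)

        return self._make(np.sqrt(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def leaky_relu(self, negative_slope: float = 0.2):
        slope = DTYPE(negative_slope)
        factor = np.where(self.data > 0, DTYPE(1.0), slope)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * factor)

        return self._make(self.data * factor, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, out):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * DTYPE(1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def take(self, indices: np.ndarray):
        """Gather rows: out[i] = self[indices[i]] (first-axis fancy indexing)."""
        idx = np.asarray(indices)

        def backward(g, out):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accum(acc)

        return self._make(self.data[idx], (self,), backward)

    def gather_cols(self, indices: np.ndarray):
        """Column gather on a 2-D tensor: out[i, ...] = self[i, indices]."""
        idx = np.asarray(indices)

        def backward(g, out):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                g2 = g.reshape(g.shape[0], idx.size)
                np.add.at(acc.T, idx.ravel(), g2.T)
                self._accum(acc)

        return self._make(self.data[:, idx], (self,), backward)

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int):
        """out[s] = sum of rows (or scalars) of self where segment_ids == s."""
        seg = np.asarray(segment_ids)
        out_shape = (num_segments,) + self.data.shape[1:]
        data = np.zeros(out_shape, dtype=DTYPE)
        np.add.at(data, seg, self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g[seg])

        return self._make(data, (self,), backward)

    def maxpool2x2(self):
        """2x2/stride-2 max pooling on an (N, C, H, W) tensor (H, W even)."""
        n, c, h, w = self.data.shape
        xr = self.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        arg = xr.argmax(axis=-1)
        out_data = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]

        def backward(g, out):
            if not self.requires_grad:
                return
            acc = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
            np.put_along_axis(acc, arg[..., None], g[..., None], axis=-1)
            acc = acc.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._accum(acc.reshape(n, c, h, w))

        return self._make(out_data, (self,), backward)

    # -- backprop -------------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE)
        else:
            self.grad = self.grad + g.astype(DTYPE, copy=False)

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad, node)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(g, o):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])

        out._backward = backward
    return out
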