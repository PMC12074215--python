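"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a ``float32`` numpy array and records the operations
applied to it; :meth:`Tensor.backward` runs the reverse sweep over the taped
graph.  The op set is deliberately small — elementwise arithmetic and
transcendentals, broadcasting, reductions, matmul, reshape/transpose/concat
and slicing — which is all the detector and its ProbIoU loss need.  Heavier
structured ops (convolution, pooling, upsampling) live in
:mod:`oeyolo.nn.functional` with hand-written backward rules.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "exp",
    "log",
    "sqrt",
    "sin",
    "cos",
    "count_flops",
    "add_flops",
]

_FLOPS: list = []  # stack of active FLOP counters


class count_flops:
    """Context manager accumulating 2x-MAC FLOP counts of matmuls/convs."""

    def __init__(self) -> None:
        self.counter = [0]

    def __enter__(self):
        _FLOPS.append(self.counter)
        return self.counter

    def __exit__(self, *exc):
        _FLOPS.remove(self.counter)
        return False


def add_flops(n: int) -> None:
    for counter in _FLOPS:
        counter[0] += int(n)


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    # make numpy defer mixed expressions (ndarray op Tensor) to the reflected
    # Tensor operators instead of broadcasting elementwise over object arrays
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, _prev: Tuple["Tensor", ...] = ()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev
        self.name = ""

    # -- introspection -----------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data: np.ndarray, parents: Tuple["Tensor", ...]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents), _prev=parents)
        return out

    def _acc(self, grad: np.ndarray) -> None:
        # store by reference, accumulate out of place: gradient arrays may be
        # shared between parents, so they are never mutated after storing
        if self.grad is None:
            self.grad = grad if grad.dtype == np.float32 else grad.astype(np.float32)
        else:
            self.grad = self.grad + grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [self]
        while stack:  # iterative DFS; graphs can be thousands of nodes deep
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._prev if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                stack.pop()
                if node.requires_grad:
                    topo.append(node)
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            had_tape = node._backward is not None
            if had_tape and node.grad is not None:
                node._backward(node.grad)
            # free the tape eagerly: closures pin large forward buffers, and
            # interior gradients are never needed once their parents have run
            node._backward = None
            node._prev = ()
            if had_tape and node is not self:
                node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other))

        def _bw(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other))

        def _bw(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._make(self.data / other.data, (self, other))

        def _bw(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(-g * self.data / (other.data * other.data), other.data.shape))

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = self._make(self.data ** p, (self,))

        def _bw(g):
            if self.requires_grad:
                self._acc(g * p * self.data ** (p - 1))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other))
        if _FLOPS:
            add_flops(2 * out.data.size * self.data.shape[-1])

        def _bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._acc(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._acc(_unbroadcast(gb, other.data.shape))

        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,))

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._acc(full)

        out._backward = _bw
        return out

    # -- elementwise functions --------------------------------------------
    def exp(self):
        out = self._make(np.exp(self.data), (self,))

        def _bw(g):
            if self.requires_grad:
                self._acc(g * out.data)

        out._backward = _bw
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,))

        def _bw(g):
            if self.requires_grad:
                self._acc(g / self.data)

        out._backward = _bw
        return out

    def sqrt(self):
        out = self._make(np.sqrt(self.data), (self,))

        def _bw(g):
            if self.requires_grad:
                self._acc(g * 0.5 / np.maximum(out.data, 1e-12))

        out._backward = _bw
        return out

    def sin(self):
        out = self._make(np.sin(self.data), (self,))

        def _bw(g):
            if self.requires_grad:
                self._acc(g * np.cos(self.data))

        out._backward = _bw
        return out

    def cos(self):
        out = self._make(np.cos(self.data), (self,))

        def _bw(g):
            if self.requires_grad:
                self._acc(g * -np.sin(self.data))

        out._backward = _bw
        return out

    def tanh(self):
        out = self._make(np.tanh(self.data), (self,))

        def _bw(g):
            if self.requires_grad:
                self._acc(g * (1.0 - out.data * out.data))

        out._backward = _bw
        return out

    def sigmoid(self):
        out = self._make(
            1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0))), (self,)
        )

        def _bw(g):
            if self.requires_grad:
                self._acc(g * out.data * (1.0 - out.data))

        out._backward = _bw
        return out

    def relu(self):
        out = self._make(np.maximum(self.data, 0.0), (self,))

        def _bw(g):
            if self.requires_grad:
                self._acc(g * (self.data > 0))

        out._backward = _bw
        return out

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = self._make(self.data * sig, (self,))

        def _bw(g):
            if self.requires_grad:
                self._acc(g * (sig * (1.0 + self.data * (1.0 - sig))))

        out._backward = _bw
        return out

    def clamp(self, lo: Optional[float] = None, hi: Optional[float] = None):
        out = self._make(np.clip(self.data, lo, hi), (self,))
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi

        def _bw(g):
            if self.requires_grad:
                self._acc(g * mask)

        out._backward = _bw
        return out

    # -- reductions and shape ops ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def _bw(g):
            if self.requires_grad:
                if axis is None:
                    self._acc(np.broadcast_to(g, self.data.shape).copy())
                else:
                    gg = g
                    if not keepdims:
                        gg = np.expand_dims(g, axis)
                    self._acc(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,))

        def _bw(g):
            if self.requires_grad:
                self._acc(g.reshape(self.data.shape))

        out._backward = _bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = self._make(self.data.transpose(axes), (self,))

        def _bw(g):
            if self.requires_grad:
                self._acc(g.transpose(inv))

        out._backward = _bw
        return out

    def softmax(self, axis: int = -1):
        """Numerically stabilized softmax (max-shift treated as a constant)."""
        shifted = self - self.data.max(axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._acc(g[tuple(idx)])

    out._backward = _bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors), _prev=tuple(tensors))

    def _bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._acc(np.take(g, i, axis=axis))

    out._backward = _bw
    return out


# free-function aliases so numeric code reads the same on arrays and tensors
def exp(x):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def sqrt(x):
    return x.sqrt() if isinstance(x, Tensor) else np.sqrt(x)


def sin(x):
    return x.sin() if isinstance(x, Tensor) else np.sin(x)


def cos(x):
    return x.cos() if isinstance(x, Tensor) else np.cos(x)
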