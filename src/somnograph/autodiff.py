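"""Minimal reverse-mode automatic differentiation on numpy arrays.

The sleep-staging network needs end-to-end gradients through graph
convolutions, dilated temporal convolutions, max-pooling attention and
batch normalization.  This module provides the small tape-based tensor
engine those layers are written against: a :class:`Tensor` wrapping an
``ndarray``, a closed set of differentiable primitives with full numpy
broadcasting, and an :class:`Adam` optimizer.

Gradients of every primitive are exercised against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concatenate",
    "stack",
    "maximum_over",
    "pairwise_edge_scores",
    "Adam",
]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple["Tensor", ...] = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- autodiff core -------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # own a copy: g may alias a view into another gradient buffer
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topological sort; graphs can be deep
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
        self.grad = np.ones_like(self.data) if grad is None else _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        if any(p.requires_grad or p._parents for p in parents):
            return Tensor(data, _parents=tuple(parents), _backward=backward)
        return Tensor(data)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other) -> "Tensor":
        return Tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)
        out_data = self.data ** e

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * e * self.data ** (e - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data
        a, b = self.data, other.data

        def backward(g: np.ndarray) -> None:
            if a.ndim == 1 or b.ndim == 1:
                raise NotImplementedError("matmul backward requires ndim >= 2")
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def swish(self) -> "Tensor":
        """x * sigmoid(x) (a.k.a. SiLU)."""
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = self.data * s

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * (s + out * (1.0 - s)))

        return Tensor._make(out, (self,), backward)

    def exp(self) -> "Tensor":
        out = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * out)

        return Tensor._make(out, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * sign)

        return Tensor._make(np.abs(self.data), (self,), backward)

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out_keep = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_keep)
        counts = mask.sum(axis=axis, keepdims=True)
        out_data = out_keep if keepdims else np.squeeze(out_keep, axis=axis)

        def backward(g: np.ndarray) -> None:
            if not keepdims:
                g = np.expand_dims(g, axis)
            # ties share gradient equally: symmetric subgradient
            self._accumulate(mask * g / counts)

        return Tensor._make(out_data, (self,), backward)

    # -- shape manipulation ------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g: np.ndarray) -> None:
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def moveaxis(self, source: int, destination: int) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accumulate(np.moveaxis(g, destination, source))

        return Tensor._make(np.moveaxis(self.data, source, destination),
                            (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), backward)

    def pad_axis(self, axis: int, before: int, after: int,
                 value: float = 0.0) -> "Tensor":
        """Constant-pad one axis (value ignored by the gradient)."""
        widths = [(0, 0)] * self.ndim
        widths[axis] = (before, after)
        out_data = np.pad(self.data, widths, constant_values=value)
        sl = [slice(None)] * self.ndim
        sl[axis] = slice(before, before + self.shape[axis])
        sl = tuple(sl)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g[sl])

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (slice, int, type(None), type(Ellipsis)))
                    for p in parts)

        def backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            if basic:  # basic indexing never repeats elements
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(out_data, (self,), backward)

    # -- composites -----------------------------------------------------------
    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - self.max(axis=axis, keepdims=True).detach()
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - self.max(axis=axis, keepdims=True).detach()
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concatenate(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else t.ndim + 1 + axis, 1)
        expanded.append(t.reshape(tuple(shape)))
    return concatenate(expanded, axis=axis)


def maximum_over(tensors: Sequence[Tensor]) -> Tensor:
    """Elementwise maximum of equally-shaped tensors (for max-pooling)."""
    return stack(tensors, axis=0).max(axis=0)


def pairwise_edge_scores(x: Tensor, w: Tensor) -> Tensor:
    """Fused edge scores relu(Σ_c w_c·|x_i − x_j|) over node pairs.

    ``x`` is (..., V, C) node features, ``w`` is (C,); the result is
    (..., V, V).  Equivalent to composing subtract/abs/mul/sum/relu but
    materializes the (..., V, V, C) pairwise array only once.
    """
    xd, wd = x.data, w.data
    diff = xd[..., :, None, :] - xd[..., None, :, :]   # (..., V, V, C)
    absdiff = np.abs(diff)
    pre = absdiff @ wd                                  # (..., V, V)
    pos = pre > 0
    out_data = pre * pos

    def backward(g: np.ndarray) -> None:
        gp = g * pos
        gw = (gp[..., None] * absdiff).reshape(-1, wd.shape[0]).sum(axis=0)
        w._accumulate(gw)
        sign = np.sign(diff)
        weighted = gp[..., None] * sign * wd            # (..., V, V, C)
        gx = weighted.sum(axis=-2) - weighted.sum(axis=-3)
        x._accumulate(gx)

    return Tensor._make(out_data, (x, w), backward)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
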