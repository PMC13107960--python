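"""Minimal reverse-mode automatic differentiation over numpy arrays.

The generator's network is small (two transformer blocks, model width 64 by
default), so a compact define-by-run tape over float64 numpy arrays is fast
enough for every training stage while keeping the whole computation exactly
reproducible.  The engine supports the operations the model needs — broadcast
arithmetic, batched matmul, softmax/log-softmax, GELU, sigmoid, reductions,
embedding lookup — each with an explicit VJP.

Gradient correctness is pinned by finite-difference tests in the suite.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf, expit as _expit

Array = np.ndarray

#: Default floating dtype for all tensors.  float32 keeps desk-scale training
#: fast; switch to float64 (``set_default_dtype``) for high-precision checks.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype).type


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")
    __array_priority__ = 100  # keep numpy from hijacking ndarray.__mul__ etc.

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _vjp: Callable[[Array], tuple[Array | None, ...]] | None = None,
    ):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._vjp = _vjp if self.requires_grad else None

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad: Array | None = None) -> None:
        """Accumulate gradients of a scalar (or supplied cotangent) output."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without cotangent requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
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
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.data.shape)
        donated: set[int] = set()  # arrays already owned by some parent.grad
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            parent_grads = node._vjp(node.grad)
            for parent, g in zip(node._parents, parent_grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    # own the buffer only if it is a fresh, un-aliased array
                    if g is node.grad or g.base is not None or id(g) in donated:
                        parent.grad = g.copy()
                    else:
                        parent.grad = g
                        donated.add(id(g))
                else:
                    parent.grad += g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        return Tensor(
            out_data,
            _parents=(self, other),
            _vjp=lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * (self ** -1.0)

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = self.data ** exponent
        return Tensor(
            out,
            _parents=(self,),
            _vjp=lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def vjp(g: Array):
            ga = g @ np.swapaxes(b, -1, -2)
            if b.ndim == 2 and a.ndim > 2:
                # batched @ weight: fold batch dims into one GEMM
                k, n = b.shape
                gb = a.reshape(-1, k).T @ g.reshape(-1, n)
            else:
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return _unbroadcast(ga, self.shape), gb

        return Tensor(a @ b, _parents=(self, other), _vjp=vjp)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        shape = shape[0] if len(shape) == 1 and isinstance(shape[0], (tuple, list)) else shape
        return Tensor(
            self.data.reshape(shape),
            _parents=(self,),
            _vjp=lambda g: (g.reshape(self.shape),),
        )

    def transpose(self, *axes):
        axes = axes[0] if len(axes) == 1 and isinstance(axes[0], (tuple, list)) else axes
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            _parents=(self,),
            _vjp=lambda g: (g.transpose(inv),),
        )

    def swapaxes(self, a: int, b: int):
        return Tensor(
            np.swapaxes(self.data, a, b),
            _parents=(self,),
            _vjp=lambda g: (np.swapaxes(g, a, b),),
        )

    def __getitem__(self, key):
        basic = all(
            isinstance(k, (slice, int, type(Ellipsis), type(None)))
            for k in (key if isinstance(key, tuple) else (key,))
        )

        def vjp(g: Array):
            out = np.zeros_like(self.data)
            if basic:  # basic slicing never repeats an index
                out[key] += g
            else:
                np.add.at(out, key, g)
            return (out,)

        return Tensor(self.data[key], _parents=(self,), _vjp=vjp)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g: Array):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor(out, _parents=(self,), _vjp=vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, _parents=(self,), _vjp=lambda g: (g * out,))

    def log(self):
        return Tensor(
            np.log(self.data), _parents=(self,), _vjp=lambda g: (g / self.data,)
        )

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, _parents=(self,), _vjp=lambda g: (g * (1 - out * out),))

    def sigmoid(self):
        out = _expit(self.data)  # numerically stable logistic
        return Tensor(out, _parents=(self,), _vjp=lambda g: (g * out * (1 - out),))

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        cdf = 0.5 * (1.0 + _erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return Tensor(x * cdf, _parents=(self,), _vjp=lambda g: (g * (cdf + x * pdf),))

    def abs(self):
        return Tensor(
            np.abs(self.data), _parents=(self,), _vjp=lambda g: (g * np.sign(self.data),)
        )


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """Create a trainable tensor; with ``rng`` and ``scale``, Gaussian init."""
    if rng is not None:
        data = rng.normal(0.0, scale if scale is not None else 0.02, size=data)
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def softmax(x: Tensor, axis: int = -1, bias: Array | None = None) -> Tensor:
    """Softmax along ``axis``; ``bias`` is a constant additive pre-activation
    (e.g. a causal mask), fused here to avoid materializing the sum node."""
    z = x.data if bias is None else x.data + bias
    shifted = z - z.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def vjp(g: Array):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - dot),)

    return Tensor(out, _parents=(x,), _vjp=vjp)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - lse

    def vjp(g: Array):
        return (g - np.exp(out) * g.sum(axis=axis, keepdims=True),)

    return Tensor(out, _parents=(x,), _vjp=vjp)


def embedding(table: Tensor, ids: Array) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add gradient."""
    ids = np.asarray(ids, dtype=np.int64)

    def vjp(g: Array):
        out = np.zeros_like(table.data)
        np.add.at(out, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        return (out,)

    return Tensor(table.data[ids], _parents=(table,), _vjp=vjp)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def vjp(g: Array):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(datas))
        )

    return Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors), _vjp=vjp)


def rms_norm(x: Tensor, gain: Tensor, eps: float = 1e-6) -> Tensor:
    """Root-mean-square normalization over the last axis, with learned gain."""
    ms = (x * x).mean(axis=-1, keepdims=True)
    return x * ((ms + eps) ** -0.5) * gain


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * ((var + eps) ** -0.5) * gain + bias


class Adam:
    """Plain Adam over a list of parameter tensors (deterministic)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
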