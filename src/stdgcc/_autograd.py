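"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model trained here is a small fixed architecture evaluated full-graph,
so a tape of a few dozen nodes per step suffices.  ``Tensor`` wraps an
ndarray; arithmetic builds the tape, ``backward()`` walks it in reverse
topological order.  Broadcasting is supported in the usual numpy sense and
gradients are summed back over broadcast axes.

Functional helpers (``exp``, ``log``, ``prelu`` ...) dispatch on input type:
given plain ndarrays they compute with numpy and return ndarrays, given
Tensors they extend the tape.  Model code is therefore written once and is
usable both for differentiable training and for plain-array unit checks.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size 1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A differentiable wrapper around a float64 ndarray (or scalar)."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor defer to the reflected Tensor operator instead
    # of numpy broadcasting over a 0-d object array
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(np.array(data, dtype=np.float64), requires_grad=True)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- autodiff --------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        def bw(g):
            self._accum(g)
            other._accum(g)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))
        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)
        out._backward = bw
        return out

    # -- reductions & elementwise ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / val)
        return out

    def clip_max(self, hi: float):
        """Upper clamp; gradient passes only where not clipped."""
        mask = self.data < hi
        out = Tensor(np.minimum(self.data, hi), _parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


# ---------------------------------------------------------------------------
# dispatching functional helpers
# ---------------------------------------------------------------------------

def exp(x):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def sqrt(x):
    return x.sqrt() if isinstance(x, Tensor) else np.sqrt(x)


def sum_(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def mean(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.mean(x, axis=axis, keepdims=keepdims)


def clip_max(x, hi: float):
    return x.clip_max(hi) if isinstance(x, Tensor) else np.minimum(x, hi)


def prelu(x, slope):
    """Parametric ReLU: ``x`` for x >= 0, ``slope * x`` otherwise.

    ``slope`` may be a learnable scalar Tensor shared across uses.
    """
    if not _is_tensor(x, slope):
        return np.where(x >= 0, x, slope * x)
    x, slope = astensor(x), astensor(slope)
    pos = x.data >= 0
    out = Tensor(np.where(pos, x.data, slope.data * x.data), _parents=(x, slope))
    def bw(g):
        x._accum(g * np.where(pos, 1.0, slope.data))
        slope._accum(np.sum(g * np.where(pos, 0.0, x.data)))
    out._backward = bw
    return out


def sigmoid(x):
    if isinstance(x, Tensor):
        val = _sigmoid_np(x.data)
        out = Tensor(val, _parents=(x,))
        out._backward = lambda g: x._accum(g * val * (1.0 - val))
        return out
    return _sigmoid_np(x)


def _sigmoid_np(x):
    # stable in both tails
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _softplus_np(x):
    return np.logaddexp(0.0, x)


def log_sigmoid(x):
    """log(sigmoid(x)) computed stably: -softplus(-x)."""
    if isinstance(x, Tensor):
        out = Tensor(-_softplus_np(-x.data), _parents=(x,))
        out._backward = lambda g: x._accum(g * _sigmoid_np(-x.data))
        return out
    return -_softplus_np(-x)


def log1m_sigmoid(x):
    """log(1 - sigmoid(x)) computed stably: -softplus(x)."""
    if isinstance(x, Tensor):
        out = Tensor(-_softplus_np(x.data), _parents=(x,))
        out._backward = lambda g: x._accum(-g * _sigmoid_np(x.data))
        return out
    return -_softplus_np(x)


def spmm(A: sp.spmatrix, x):
    """Sparse @ dense product with a constant sparse left factor."""
    if isinstance(x, Tensor):
        out = Tensor(A @ x.data, _parents=(x,))
        out._backward = lambda g: x._accum(A.T @ g)
        return out
    return A @ x


def matmul(a, b):
    if _is_tensor(a, b):
        return astensor(a) @ astensor(b)
    return a @ b


def value(x) -> np.ndarray:
    """Underlying ndarray of a Tensor, or the array itself."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
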