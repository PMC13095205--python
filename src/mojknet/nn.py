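"""Minimal reverse-mode automatic differentiation over numpy arrays.

The pipeline's three learned stages (multimodal autoencoder, jumping-
knowledge graph branches, graph attention classifier) are dense, full-batch
models on cohorts of a few hundred patients, so a compact float64 tape
engine is sufficient and keeps results bit-reproducible for a given seed.
Gradients are verified against central finite differences in the test
suite.

Only the operations those models need are implemented: matmul, broadcasted
add/sub/mul/div, transpose, relu / leaky relu, exp, log, sum/mean, elementwise
maximum, column concatenation and row-softmax / cross-entropy composites.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Linear", "Adam", "relu", "leaky_relu",
           "concat", "maximum", "softmax_rows", "masked_cross_entropy",
           "weighted_mse", "dropout_mask", "params_checksum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, prev, backward) -> "Tensor":
        req = any(p.requires_grad for p in prev)
        out = Tensor(data, requires_grad=req, _prev=tuple(p for p in prev if p.requires_grad))
        if req:
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))
        return self._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        return self._make(self.data @ other.data, (self, other), backward)

    @property
    def T(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g.T)
        return self._make(self.data.T, (self,), backward)

    # -- nonlinearities and reductions ----------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)
        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)
        return self._make(np.log(self.data), (self,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                grad = np.asarray(g)
                if axis is not None and not keepdims:
                    grad = np.expand_dims(grad, axis)
                self._accum(np.broadcast_to(grad, self.shape).copy())
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- autodiff driver -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def relu(x: Tensor) -> Tensor:
    mask = (x.data > 0).astype(np.float64)
    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)
    return x._make(x.data * mask, (x,), backward)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    factor = np.where(x.data > 0, 1.0, slope)
    def backward(g):
        if x.requires_grad:
            x._accum(g * factor)
    return x._make(x.data * factor, (x,), backward)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise maximum; on exact ties the gradient goes to ``a``."""
    take_a = a.data >= b.data
    def backward(g):
        if a.requires_grad:
            a._accum(g * take_a)
        if b.requires_grad:
            b._accum(g * ~take_a)
    return a._make(np.where(take_a, a.data, b.data), (a, b), backward)


def concat(parts: list[Tensor]) -> Tensor:
    """Column-wise concatenation of 2-D tensors."""
    widths = [p.shape[1] for p in parts]
    offsets = np.cumsum([0] + widths)
    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                p._accum(g[:, lo:hi])
    data = np.concatenate([p.data for p in parts], axis=1)
    return parts[0]._make(data, tuple(parts), backward)


def softmax_rows(x: Tensor) -> Tensor:
    """Row softmax (numerically stabilized; the shift is gradient-free)."""
    shift = Tensor(x.data.max(axis=1, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=1, keepdims=True)


def _log_softmax(x: Tensor) -> Tensor:
    shift = Tensor(x.data.max(axis=1, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=1, keepdims=True).log()


def masked_cross_entropy(logits: Tensor, labels: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean cross-entropy over the rows selected by the boolean ``mask``.

    Transductive training computes logits for every node but only labeled
    training nodes contribute to the loss.
    """
    n, c = logits.shape
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    weights = mask.astype(np.float64)[:, None] / max(mask.sum(), 1)
    logp = _log_softmax(logits)
    return -(logp * Tensor(onehot * weights)).sum()


def weighted_mse(x: np.ndarray, x_hat: Tensor) -> Tensor:
    """Mean squared reconstruction error of one modality."""
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    diff = x_hat - Tensor(x)
    return (diff * diff).mean()


def dropout_mask(rng: np.random.Generator, shape: tuple[int, ...], p: float) -> Tensor:
    """Inverted-dropout mask: zeros with probability p, survivors scaled by 1/(1-p)."""
    if p <= 0:
        return Tensor(np.ones(shape))
    keep = rng.random(shape) >= p
    return Tensor(keep / (1.0 - p))


class Linear:
    """Dense layer with Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.W = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = Parameter(np.zeros((1, n_out))) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    @property
    def params(self) -> list[Parameter]:
        return [self.W] if self.b is None else [self.W, self.b]


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Parameter], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def params_checksum(params: list[Parameter]) -> str:
    """Stable hex digest of a parameter list (for leakage/determinism checks)."""
    import hashlib

    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()
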