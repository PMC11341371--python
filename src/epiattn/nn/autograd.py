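"""Minimal reverse-mode automatic differentiation over numpy arrays.

Purpose-built for the model in this package: dense/batched matmul,
broadcasting elementwise arithmetic, softmax/log-softmax, layer norm,
embedding lookup, 1-D sliding-window convolution, axis reductions, and a
gradient reversal op.  Float32 throughout; gradients accumulate into
``Tensor.grad`` after :meth:`Tensor.backward`.

The engine records a tape only when some input requires gradients; wrap
evaluation passes in :func:`no_grad` to skip tape construction entirely.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

DTYPE = np.float32

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the block (evaluation mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        needs = _grad_enabled and any(p.requires_grad for p in parents)
        out.requires_grad = needs
        out._parents = tuple(parents) if needs else ()
        out._backward = backward if needs else None
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs here are deep (per-layer chains)
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
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node._parents:  # free intermediate grads to bound memory
                    node.grad = None

    # -- elementwise arithmetic ---------------------------------------------
    @staticmethod
    def _as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))

    def __add__(self, other):
        other = Tensor._as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-Tensor._as_tensor(other))

    def __rsub__(self, other):
        return Tensor._as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._as_tensor(other)
        return self * (other ** -1.0)

    def __rtruediv__(self, other):
        return Tensor._as_tensor(other) * (self ** -1.0)

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._make(out_data, (a,), backward)

    # -- linear algebra ------------------------------------------------------
    def __matmul__(self, other):
        other = Tensor._as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        a = self
        orig = a.shape

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(orig))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        axes = axes or tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, key):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, key, g)
                a._accumulate(full)

        return Tensor._make(a.data[key], (a,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).astype(DTYPE))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.shape).astype(DTYPE))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the (first) argmax."""
        a = self
        idx = np.argmax(a.data, axis=axis)
        out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def backward(g):
            if not a.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            full = np.zeros_like(a.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), gg, axis=axis)
            a._accumulate(full)

        return Tensor._make(out_data, (a,), backward)

    # -- nonlinearities --------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def relu(self):
        a = self
        mask = (a.data > 0).astype(DTYPE)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def gelu(self):
        """tanh-approximation GELU."""
        a = self
        c = np.sqrt(2.0 / np.pi).astype(DTYPE)
        u = c * (a.data + 0.044715 * a.data**3)
        t = np.tanh(u)
        out_data = 0.5 * a.data * (1.0 + t)

        def backward(g):
            if a.requires_grad:
                du = c * (1.0 + 3 * 0.044715 * a.data**2)
                grad = 0.5 * (1.0 + t) + 0.5 * a.data * (1.0 - t**2) * du
                a._accumulate(g * grad)

        return Tensor._make(out_data.astype(DTYPE), (a,), backward)


# -- fused composite ops -----------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            gx = p * (g - (g * p).sum(axis=axis, keepdims=True))
            x._accumulate(gx.astype(DTYPE))

    return Tensor._make(p.astype(DTYPE), (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    p = np.exp(out)

    def backward(g):
        if x.requires_grad:
            gx = g - p * g.sum(axis=axis, keepdims=True)
            x._accumulate(gx.astype(DTYPE))

    return Tensor._make(out.astype(DTYPE), (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            n = x.data.shape[-1]
            gh = g * gamma.data
            gx = inv / n * (
                n * gh
                - gh.sum(axis=-1, keepdims=True)
                - xhat * (gh * xhat).sum(axis=-1, keepdims=True)
            )
            x._accumulate(gx.astype(DTYPE))

    return Tensor._make(out.astype(DTYPE), (x, gamma, beta), backward)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)

    def backward(g):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, ids.reshape(-1), g.reshape(-1, weight.data.shape[1]))
            weight._accumulate(full)

    return Tensor._make(weight.data[ids], (weight,), backward)


def conv1d_text(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Width-w 1-D convolution over positions for TextCNN.

    x: (B, L, D); weight: (w*D, F); bias: (F,) -> output (B, L-w+1, F).
    """
    B, L, D = x.data.shape
    F = weight.data.shape[1]
    w = weight.data.shape[0] // D
    Lout = L - w + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, w, axis=1)  # (B,Lout,D,w)
    flat = win.transpose(0, 1, 3, 2).reshape(B, Lout, w * D)
    out = flat @ weight.data + bias.data

    def backward(g):
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = flat.reshape(-1, w * D).T @ g.reshape(-1, F)
            weight._accumulate(gw.astype(DTYPE))
        if x.requires_grad:
            gflat = (g @ weight.data.T).reshape(B, Lout, w, D)
            gx = np.zeros_like(x.data)
            for i in range(w):
                gx[:, i : i + Lout, :] += gflat[:, :, i, :]
            x._accumulate(gx)

    return Tensor._make(out.astype(DTYPE), (x, weight, bias), backward)


def grad_reverse(x: Tensor, lam: float) -> Tensor:
    """Gradient reversal: identity forward, gradient scaled by ``-lam`` backward."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")

    def backward(g):
        if x.requires_grad:
            x._accumulate(-lam * g)

    return Tensor._make(x.data.copy(), (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(DTYPE) / (1.0 - rate)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * keep)

    return Tensor._make(x.data * keep, (x,), backward)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out, tuple(tensors), backward)


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  ignore_index: int | None = None) -> Tensor:
    """Mean negative log-likelihood over non-ignored targets.

    logits: (..., C); targets: integer array of logits.shape[:-1].
    """
    targets = np.asarray(targets)
    lp = log_softmax(logits, axis=-1)
    flat_lp = lp.reshape(-1, logits.shape[-1])
    flat_t = targets.reshape(-1)
    if ignore_index is not None:
        mask = flat_t != ignore_index
    else:
        mask = np.ones_like(flat_t, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no targets to compute loss over")
    safe_t = np.where(mask, flat_t, 0)
    picked = flat_lp[np.arange(flat_t.size), safe_t]
    return -(picked * Tensor(mask.astype(DTYPE))).sum() * (1.0 / n)
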