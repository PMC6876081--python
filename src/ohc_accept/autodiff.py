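"""A compact reverse-mode automatic-differentiation engine over numpy.

The recurrent co-attention encoder needs gradients through LSTM
recurrences, batched matrix products, masked softmaxes and concatenation.
This module provides exactly that: a :class:`Tensor` wrapping an ndarray,
a tape built implicitly by the ops below, and :meth:`Tensor.backward`
running the reverse sweep in topological order.  Gradients are checked
against central finite differences in the test suite.

Backward closures receive the upstream gradient as an argument and never
capture their own output tensor, so a released graph is freed by
reference counting alone (no cycles for the garbage collector to chase);
intermediate gradients are dropped as soon as the sweep has consumed
them, keeping peak memory proportional to one batch, not one epoch.

Matmul supports the three layouts the model uses: 2D @ 2D, batched
3D @ 3D with equal leading dimension, and 3D @ 2D (a shared weight
applied to every batch element).  Inference can run without taping via
:func:`no_grad`.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor", "no_grad", "tensor", "concat", "stack", "masked_softmax",
    "softmax_cross_entropy", "lstm_sequence", "dropout_mask",
]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable taping inside the block (inference / feature extraction)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED[-1]
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- basics ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # materialised copy: g is often a view into a child's grad
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Reverse sweep from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS: sequences make recursion depth unbounded
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if pending:
                stack_.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                node.grad = None  # only leaves keep their gradients

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = tensor(other)
        a, b = self, other
        out = Tensor(
            a.data + b.data,
            requires_grad=a.requires_grad or b.requires_grad,
            parents=(a, b),
        )

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self
        out = Tensor(-a.data, requires_grad=a.requires_grad, parents=(a,))
        out._backward = lambda g: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        a, b = self, other
        out = Tensor(
            a.data * b.data,
            requires_grad=a.requires_grad or b.requires_grad,
            parents=(a, b),
        )
        ad_, bd = a.data, b.data

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * bd, ad_.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * ad_, bd.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = tensor(other)
        x, w = self, other
        a, b = x.data, w.data
        out = Tensor(
            np.matmul(a, b),
            requires_grad=x.requires_grad or w.requires_grad,
            parents=(x, w),
        )

        def backward(g):
            if x.requires_grad:
                x._accum(_unbroadcast(np.matmul(g, np.swapaxes(b, -1, -2)), a.shape))
            if w.requires_grad:
                w._accum(_unbroadcast(np.matmul(np.swapaxes(a, -1, -2), g), b.shape))

        out._backward = backward
        return out

    # -- shaping --------------------------------------------------------
    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        a = self
        out = Tensor(
            np.transpose(a.data, axes),
            requires_grad=a.requires_grad,
            parents=(a,),
        )
        inv = np.argsort(axes)
        out._backward = lambda g: a._accum(np.transpose(g, inv))
        return out

    def reshape(self, *shape):
        a = self
        out = Tensor(
            a.data.reshape(*shape),
            requires_grad=a.requires_grad,
            parents=(a,),
        )
        orig = a.data.shape
        out._backward = lambda g: a._accum(g.reshape(orig))
        return out

    def __getitem__(self, key):
        a = self
        out = Tensor(a.data[key], requires_grad=a.requires_grad, parents=(a,))
        fancy = isinstance(key, np.ndarray) or (
            isinstance(key, tuple) and any(isinstance(k, np.ndarray) for k in key)
        )

        def backward(g):
            full = np.zeros_like(a.data)
            if fancy:  # indices may repeat
                np.add.at(full, key, g)
            else:
                full[key] += g
            a._accum(full)

        out._backward = backward
        return out

    def pad_axis(self, axis: int, target: int):
        """Zero-pad one axis up to ``target`` length (no-op if already there)."""
        cur = self.data.shape[axis]
        if cur == target:
            return self
        if cur > target:
            raise ValueError(f"cannot pad axis of length {cur} down to {target}")
        widths = [(0, 0)] * self.data.ndim
        widths[axis] = (0, target - cur)
        a = self
        out = Tensor(
            np.pad(a.data, widths),
            requires_grad=a.requires_grad,
            parents=(a,),
        )
        sl = [slice(None)] * a.data.ndim
        sl[axis] = slice(0, cur)
        sl = tuple(sl)
        out._backward = lambda g: a._accum(g[sl])
        return out

    # -- reductions & nonlinearities ------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out = Tensor(
            a.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=a.requires_grad,
            parents=(a,),
        )
        shape = a.data.shape

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, shape).copy())

        out._backward = backward
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    def tanh(self):
        a = self
        y = np.tanh(a.data)
        out = Tensor(y, requires_grad=a.requires_grad, parents=(a,))
        out._backward = lambda g: a._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        a = self
        y = expit(a.data)
        out = Tensor(y, requires_grad=a.requires_grad, parents=(a,))
        out._backward = lambda g: a._accum(g * y * (1.0 - y))
        return out

    def log(self):
        a = self
        out = Tensor(np.log(a.data), requires_grad=a.requires_grad, parents=(a,))
        out._backward = lambda g: a._accum(g / a.data)
        return out


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(x, dtype=np.float64) -> Tensor:
    return Tensor(np.asarray(x, dtype=dtype), requires_grad=True)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in ts], axis=axis),
        requires_grad=any(t.requires_grad for t in ts),
        parents=tuple(ts),
    )
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)
    ndim = out.data.ndim

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = backward
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [tensor(t) for t in tensors]
    out = Tensor(
        np.stack([t.data for t in ts], axis=axis),
        requires_grad=any(t.requires_grad for t in ts),
        parents=tuple(ts),
    )

    def backward(g):
        slices = np.moveaxis(g, axis, 0)
        for t, gt in zip(ts, slices):
            if t.requires_grad:
                t._accum(gt)

    out._backward = backward
    return out


def masked_softmax(x: Tensor, mask: np.ndarray, axis: int) -> Tensor:
    """Softmax along ``axis`` restricted to positions where mask is 1.

    Masked positions get exactly zero weight and are excluded from the
    normaliser.  A slice with no unmasked entries raises.  Numerically
    stabilised by subtracting the per-slice max over unmasked entries.
    """
    mask = np.asarray(mask, dtype=bool)
    mask = np.broadcast_to(mask, x.data.shape)
    if not np.all(mask.any(axis=axis)):
        raise ValueError("masked_softmax: a slice has no unmasked entries")
    neg = np.where(mask, x.data, -np.inf)
    m = neg.max(axis=axis, keepdims=True)
    e = np.exp(np.where(mask, x.data - m, -np.inf))
    e = np.where(mask, e, 0.0)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, requires_grad=x.requires_grad, parents=(x,))

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    out._backward = backward
    return out


def softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, reduction: str = "sum"
) -> tuple[Tensor, np.ndarray]:
    """Cross-entropy between softmax(logits) and integer labels.

    Returns (loss, probabilities).  ``reduction`` is "sum" (the loss as a
    sum over the batch) or "mean".
    """
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = labels.shape[0]
    eps = 1e-12
    picked = np.clip(p[np.arange(n), labels], eps, 1.0)
    val = -np.log(picked).sum()
    scale = 1.0 / n if reduction == "mean" else 1.0
    out = Tensor(val * scale, requires_grad=logits.requires_grad, parents=(logits,))

    def backward(g):
        gp = p.copy()
        gp[np.arange(n), labels] -= 1.0
        logits._accum(gp * (float(g) * scale))

    out._backward = backward
    return out, p


def lstm_sequence(X: Tensor, mask: np.ndarray, W: Tensor, b: Tensor, l: int) -> Tensor:
    """LSTM over a batch of sequences as one fused tape node.

    X is B x T x d; mask is B x T with 1 at real positions — PAD steps
    carry the previous hidden and cell state through unchanged.  W is
    (d + l) x 4l with gate order (input, forget, cell, output), b is 4l.
    Returns the per-step hidden states H (B x T x l); the state at each
    sequence's last real step is H[:, -1] because of the mask carrying.

    The backward closure is hand-written backpropagation through time,
    fused for speed (per-op taping of a long recurrence is prohibitively
    slow in pure numpy); it is validated against finite differences in
    the test suite.
    """
    Xd, Wd, bd = X.data, W.data, b.data
    B, T, d = Xd.shape
    dtype = Wd.dtype
    Wx, Wh = Wd[:d], Wd[d:]
    # time-major internals: per-step slices are contiguous
    Mt = np.ascontiguousarray(np.asarray(mask, dtype=dtype).T)[:, :, None]  # T,B,1
    Xt = np.ascontiguousarray(Xd.transpose(1, 0, 2))                        # T,B,d
    # input-side projection for all steps in one GEMM; the loop only
    # carries the small recurrent product
    Zx = (Xt.reshape(T * B, d) @ Wx).reshape(T, B, 4 * l) + bd
    H = np.empty((T, B, l), dtype=dtype)
    C = np.empty((T, B, l), dtype=dtype)
    G = np.empty((T, B, 4 * l), dtype=dtype)   # gates i, f, g, o
    TC = np.empty((T, B, l), dtype=dtype)      # tanh of the fresh cell state
    h = np.zeros((B, l), dtype=dtype)
    c = np.zeros((B, l), dtype=dtype)
    for t in range(T):
        z = Zx[t] + h @ Wh
        i = expit(z[:, :l])
        f = expit(z[:, l : 2 * l])
        g = np.tanh(z[:, 2 * l : 3 * l])
        o = expit(z[:, 3 * l :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        m = Mt[t]
        h = m * (o * tc) + (1.0 - m) * h
        c = m * c_new + (1.0 - m) * c
        G[t, :, :l], G[t, :, l : 2 * l] = i, f
        G[t, :, 2 * l : 3 * l], G[t, :, 3 * l :] = g, o
        TC[t] = tc
        H[t] = h
        C[t] = c
    del Zx
    out = Tensor(
        np.ascontiguousarray(H.transpose(1, 0, 2)),
        requires_grad=X.requires_grad or W.requires_grad or b.requires_grad,
        parents=(X, W, b),
    )

    def backward(grad):
        dHt = np.ascontiguousarray(grad.transpose(1, 0, 2))  # T,B,l
        dZ = np.empty((T, B, 4 * l), dtype=dtype)
        zero = np.zeros((B, l), dtype=dtype)
        WhT = np.ascontiguousarray(Wh.T)
        dh = np.zeros((B, l), dtype=dtype)
        dc = np.zeros((B, l), dtype=dtype)
        for t in range(T - 1, -1, -1):
            m = Mt[t]
            c_prev = C[t - 1] if t > 0 else zero
            Gt = G[t]
            i, f = Gt[:, :l], Gt[:, l : 2 * l]
            g, o = Gt[:, 2 * l : 3 * l], Gt[:, 3 * l :]
            tc = TC[t]
            dht = dHt[t] + dh
            dh_raw = dht * m
            dh_prev = dht * (1.0 - m)
            do = dh_raw * tc
            dc_new = dh_raw * o * (1.0 - tc * tc) + dc * m
            dc_prev = dc * (1.0 - m) + dc_new * f
            dz = dZ[t]
            np.multiply(dc_new * g, i * (1.0 - i), out=dz[:, :l])
            np.multiply(dc_new * c_prev, f * (1.0 - f), out=dz[:, l : 2 * l])
            np.multiply(dc_new * i, 1.0 - g * g, out=dz[:, 2 * l : 3 * l])
            np.multiply(do * o, 1.0 - o, out=dz[:, 3 * l :])
            dh = dh_prev + dz @ WhT
            dc = dc_prev
        if W.requires_grad or b.requires_grad:
            dZ2 = dZ.reshape(T * B, 4 * l)
            dW = np.empty_like(Wd)
            dW[:d] = Xt.reshape(T * B, d).T @ dZ2
            # recurrent part: pair dz_t with the previous step's h
            Hprev = np.concatenate([np.zeros((1, B, l), dtype=dtype), H[:-1]], axis=0)
            dW[d:] = Hprev.reshape(T * B, l).T @ dZ2
            if W.requires_grad:
                W._accum(dW)
            if b.requires_grad:
                b._accum(dZ2.sum(axis=0))
        if X.requires_grad:
            dXt = (dZ.reshape(T * B, 4 * l) @ Wx.T).reshape(T, B, d)
            X._accum(dXt.transpose(1, 0, 2))

    out._backward = backward
    return out


def dropout_mask(rng: np.random.Generator, shape, rate: float, dtype=np.float64) -> np.ndarray:
    """Inverted-dropout multiplier: keep with prob 1-rate, rescale kept units."""
    if rate <= 0:
        return np.ones(shape, dtype=dtype)
    keep = 1.0 - rate
    return (rng.random(shape) < keep).astype(dtype) / np.asarray(keep, dtype=dtype)
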