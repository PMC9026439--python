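"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine records a tape of :class:`Tensor` nodes; calling
:meth:`Tensor.backward` on a scalar loss walks the tape in reverse
topological order and accumulates gradients into every parameter that
was created with ``requires_grad=True``.

Only the operations needed by a dual-branch convolutional classifier are
implemented: 'same' 3x3 convolution (im2col + GEMM), batch
normalisation, ReLU, 2x2/stride-2 max pooling, dropout, dense layers,
elementwise add / scalar scale / channel concatenation (the two
feature-sharing and three fusion modes), and a fused softmax
cross-entropy that accepts soft label vectors.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ContractError, NumericError

__all__ = [
    "Tensor", "add", "scale", "concat", "relu", "reshape", "linear",
    "conv2d", "maxpool2", "dropout", "batchnorm2d", "softmax",
    "softmax_cross_entropy",
]


class Tensor:
    """A NumPy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ContractError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit the recursion limit
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

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


# ---------------------------------------------------------------- arithmetic

def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ContractError(f"add: shape mismatch {a.data.shape} vs {b.data.shape}")

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return _node(a.data + b.data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    s = float(s)

    def backward(g):
        _accum(a, g * s)

    return _node(a.data * s, (a,), backward)


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    na = a.data.shape[axis]

    def backward(g):
        ga, gb = np.split(g, [na], axis=axis)
        _accum(a, ga)
        _accum(b, gb)

    return _node(np.concatenate([a.data, b.data], axis=axis), (a, b), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _node(a.data * mask, (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape

    def backward(g):
        _accum(a, g.reshape(old))

    return _node(a.data.reshape(shape), (a,), backward)


# ---------------------------------------------------------------- dense

def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """``x @ w + b`` with ``x`` of shape (N, D), ``w`` (D, O), ``b`` (O,)."""
    if x.data.shape[1] != w.data.shape[0]:
        raise ContractError(
            f"linear: input dim {x.data.shape[1]} != weight dim {w.data.shape[0]}")

    def backward(g):
        _accum(x, g @ w.data.T)
        _accum(w, x.data.T @ g)
        _accum(b, g.sum(axis=0))

    return _node(x.data @ w.data + b.data, (x, w, b), backward)


# ---------------------------------------------------------------- convolution

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))      # N,C,H,W,k,k
    return np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)
                                ).reshape(n * h * w, c * k * k)


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int = 1) -> Tensor:
    """'Same' convolution, stride 1, square kernel (im2col + GEMM)."""
    n, c, h, wd = x.data.shape
    o, ci, k, _ = w.data.shape
    if ci != c:
        raise ContractError(f"conv2d: {c} input channels but kernel expects {ci}")
    cols = _im2col(x.data, k, pad)
    wm = w.data.reshape(o, -1)
    out = (cols @ wm.T + b.data).reshape(n, h, wd, o).transpose(0, 3, 1, 2)

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
        _accum(w, (gm.T @ cols).reshape(w.data.shape))
        _accum(b, gm.sum(axis=0))
        if x.requires_grad:
            dcols = (gm @ wm).reshape(n, h, wd, c, k, k)
            dxp = np.zeros((n, c, h + 2 * pad, wd + 2 * pad), dtype=x.data.dtype)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + h, j:j + wd] += dcols[:, :, :, :, i, j
                                                          ].transpose(0, 3, 1, 2)
            _accum(x, dxp[:, :, pad:pad + h, pad:pad + wd] if pad else dxp)

    return _node(np.ascontiguousarray(out), (x, w, b), backward)


# ---------------------------------------------------------------- pooling

def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even.

    Gradient is routed to every element attaining the window maximum
    (ties are measure-zero for continuous activations).
    """
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ContractError(f"maxpool2: odd spatial size ({h}, {w})")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))

    def backward(g):
        mask = xr == out[:, :, :, None, :, None]
        gx = (mask * g[:, :, :, None, :, None]).reshape(n, c, h, w)
        _accum(x, gx)

    return _node(out, (x,), backward)


# ---------------------------------------------------------------- dropout

def dropout(x: Tensor, rate: float, rng: np.random.Generator | None,
            train: bool) -> Tensor:
    """Inverted dropout; identity when ``train`` is False or rate is 0."""
    if not train or rate == 0.0:
        return x
    if rng is None:
        raise ContractError("dropout in train mode requires an rng")
    keep = (rng.random(x.data.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)

    def backward(g):
        _accum(x, g * keep)

    return _node(x.data * keep, (x,), backward)


# ---------------------------------------------------------------- batch norm

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                train: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, H, W) with affine params.

    In train mode the batch statistics are used and the running estimates
    are updated in place (unbiased variance, momentum-weighted); in eval
    mode the running estimates are used.
    """
    n, c, h, w = x.data.shape
    gm = gamma.data.reshape(1, c, 1, 1)
    if train:
        axes = (0, 2, 3)
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        cnt = n * h * w
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * (var * cnt / max(cnt - 1, 1))
        invstd = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mean.reshape(1, c, 1, 1)) * invstd.reshape(1, c, 1, 1)

        def backward(g):
            _accum(gamma, (g * xhat).sum(axis=axes))
            _accum(beta, g.sum(axis=axes))
            if x.requires_grad:
                dxhat = g * gm
                m1 = dxhat.sum(axis=axes, keepdims=True)
                m2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                dx = (dxhat - (m1 + xhat * m2) / cnt) * invstd.reshape(1, c, 1, 1)
                _accum(x, dx)
    else:
        invstd = 1.0 / np.sqrt(running_var + eps)
        xhat = (x.data - running_mean.reshape(1, c, 1, 1)) * invstd.reshape(1, c, 1, 1)

        def backward(g):
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
            _accum(beta, g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                _accum(x, g * gm * invstd.reshape(1, c, 1, 1))

    out = xhat * gm + beta.data.reshape(1, c, 1, 1)
    return _node(out.astype(x.data.dtype, copy=False), (x, gamma, beta), backward)


# ---------------------------------------------------------------- loss

def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis (plain ndarray)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy  -1/N * sum_i sum_c y_ic log p_ic.

    ``targets`` may be one-hot or soft (Mixup) label vectors; rows must
    sum to 1.
    """
    y = np.asarray(targets, dtype=logits.data.dtype)
    if y.shape != logits.data.shape:
        raise ContractError(
            f"cross-entropy: targets {y.shape} vs logits {logits.data.shape}")
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    n = logits.data.shape[0]
    loss = -(y * logp).sum() / n
    if not np.isfinite(loss):
        raise NumericError("non-finite cross-entropy loss")
    p = np.exp(logp)

    def backward(g):
        _accum(logits, g * (p - y) / n)

    return _node(np.asarray(loss, dtype=logits.data.dtype), (logits,), backward)
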