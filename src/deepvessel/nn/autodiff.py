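"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to train the diffusion noise-prediction U-Net on a
CPU: broadcast-aware elementwise ops, batched matmul, same-padded 3x3/1x1
convolution via im2col, reductions, reshapes, and a couple of structural
ops (nearest-neighbor 2x upsampling, channel concatenation).  Gradients are
accumulated by a topological-order sweep over the recorded graph.

Gradient correctness is verified against central finite differences in the
test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor", "no_grad",
    "add", "mul", "sub", "neg", "pow_", "div",
    "matmul", "conv2d", "silu", "exp", "log",
    "sum_", "mean", "reshape", "transpose",
    "softmax", "avg_pool2", "upsample2", "concat", "pad_hw",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # convenience operators (forwarding to module-level ops)
    def __add__(self, other):
        return add(self, _wrap(other))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __neg__(self):
        return neg(self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph recording (inference mode); frees im2col buffers eagerly."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))
    return _make(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))
    return _make(a.data * b.data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        _accum(a, -g)
    return _make(-a.data, (a,), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    return add(a, neg(b))


def pow_(a: Tensor, p: float) -> Tensor:
    def backward(g):
        _accum(a, g * p * np.power(a.data, p - 1))
    return _make(np.power(a.data, p), (a,), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    return mul(a, pow_(b, -1.0))


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        _accum(a, g * out_data)
    return _make(out_data, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        _accum(a, g / a.data)
    return _make(np.log(a.data), (a,), backward)


def silu(a: Tensor) -> Tensor:
    sig = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * sig * (1 + a.data * (1 - sig)))
    return _make(a.data * sig, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        _accum(a, _unbroadcast(ga, a.data.shape))
        _accum(b, _unbroadcast(gb, b.data.shape))
    return _make(np.matmul(a.data, b.data), (a, b), backward)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
            return
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            for ax in sorted(a_pos(ax, a.data.ndim) for ax in axes):
                g = np.expand_dims(g, ax)
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    def a_pos(ax, nd):
        return ax % nd

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        count = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), Tensor(1.0 / count))


def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        _accum(a, g.reshape(a.data.shape))
    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, g.transpose(inv))
    return _make(a.data.transpose(axes), (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        _accum(a, out_data * (g - dot))
    return _make(out_data, (a,), backward)


# --- convolution ----------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H, W, C*kh*kw) with same padding."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, h, w, kh, kw),
        strides=(s[0], s[1], s[2], s[3], s[2], s[3]),
        writeable=False,
    )
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, w, c * kh * kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 2D convolution (cross-correlation).

    ``x``: (N, C, H, W); ``w``: (O, C, kh, kw) with odd kh == kw;
    ``b``: (O,) or None.
    """
    n, c, h, wd = x.data.shape
    o, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, weight {c2}")
    pad = kh // 2
    cols = _im2col(x.data, kh, kw, pad)  # (N, H, W, C*kh*kw)
    wmat = w.data.reshape(o, -1)  # (O, C*kh*kw)
    out_data = cols @ wmat.T  # (N, H, W, O)
    if b is not None:
        out_data = out_data + b.data
    out_data = out_data.transpose(0, 3, 1, 2)

    def backward(g):
        gt = g.transpose(0, 2, 3, 1)  # (N, H, W, O)
        gw = gt.reshape(-1, o).T @ cols.reshape(-1, c * kh * kw)
        _accum(w, gw.reshape(w.data.shape))
        if b is not None:
            _accum(b, gt.sum(axis=(0, 1, 2)))
        gcols = gt @ wmat  # (N, H, W, C*kh*kw)
        gcols = gcols.reshape(n, h, wd, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gx = np.zeros((n, c, h + 2 * pad, wd + 2 * pad))
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i : i + h, j : j + wd] += gcols[:, :, :, :, i, j]
        _accum(x, gx[:, :, pad : pad + h, pad : pad + wd] if pad else gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


# --- structural ops -------------------------------------------------------


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling on (N, C, H, W) with even H, W."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2 requires even spatial dims")
    r = reshape(x, (n, c, h // 2, 2, w // 2, 2))
    return mean(r, axis=(3, 5))


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x upsampling on (N, C, H, W)."""
    n, c, h, w = x.data.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        _accum(x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
    return _make(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])
    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def pad_hw(x: Tensor, ph: int, pw: int) -> Tensor:
    """Zero-pad the two trailing spatial axes of (N, C, H, W)."""
    def backward(g):
        _accum(x, g[:, :, : x.data.shape[2], : x.data.shape[3]])
    return _make(np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw))), (x,), backward)
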