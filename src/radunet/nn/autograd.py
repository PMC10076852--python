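"""Minimal reverse-mode automatic differentiation on numpy arrays.

All tensors are dense float32 numpy arrays; network activations use the
NCHW layout (batch, channels, height, width).  Convolutions are stride-1
only, which lets the input gradient be computed as a correlation with the
180-degree-rotated kernel instead of a scatter-add, keeping the whole
backward pass inside BLAS-backed matrix products.

The graph is a tape: each op returns a new :class:`Tensor` holding a
closure that accumulates gradients into its parents.  ``Tensor.backward``
runs the closures in reverse topological order.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """A node in the autodiff graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep U-Nets overflow the recursion limit
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
        self.accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _as_tensor(-1.0)))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, _as_tensor(-1.0)))

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return mul(self, _as_tensor(-1.0))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise ------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a.accumulate(_unbroadcast(g, a.shape))
        b.accumulate(_unbroadcast(g, b.shape))

    return _node(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a.accumulate(_unbroadcast(g * b.data, a.shape))
        b.accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a.accumulate(_unbroadcast(g / b.data, a.shape))
        b.accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _node(a.data / b.data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a.accumulate(g * mask)

    return _node(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable two-sided form
    y = np.empty_like(a.data)
    pos = a.data >= 0
    y[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    e = np.exp(a.data[~pos])
    y[~pos] = e / (1.0 + e)

    def backward(g):
        a.accumulate(g * y * (1.0 - y))

    return _node(y, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        a.accumulate(g / a.data)

    return _node(np.log(a.data), (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only inside the open interval."""
    inside = (a.data > lo) & (a.data < hi)

    def backward(g):
        a.accumulate(g * inside)

    return _node(np.clip(a.data, lo, hi), (a,), backward)


# -- reductions and shape ops ------------------------------------------------

def reduce_sum(a: Tensor, axes=None, keepdims: bool = False) -> Tensor:
    def backward(g):
        if axes is not None and not keepdims:
            g = np.expand_dims(g, axes)
        a.accumulate(np.broadcast_to(g, a.shape))

    return _node(a.data.sum(axis=axes, keepdims=keepdims), (a,), backward)


def reduce_mean(a: Tensor, axes=None, keepdims: bool = False) -> Tensor:
    denom = a.data.size if axes is None else np.prod([a.shape[i] for i in np.atleast_1d(axes)])

    def backward(g):
        if axes is not None and not keepdims:
            g = np.expand_dims(g, axes)
        a.accumulate(np.broadcast_to(g, a.shape) / DTYPE(denom))

    return _node(a.data.mean(axis=axes, keepdims=keepdims), (a,), backward)


def reduce_max(a: Tensor, axes, keepdims: bool = True) -> Tensor:
    """Max over ``axes``; on ties the gradient is split evenly among argmaxes."""
    out = a.data.max(axis=axes, keepdims=True)
    mask = (a.data == out).astype(DTYPE)
    with np.errstate(invalid="ignore"):  # NaN inputs never equal their max
        mask /= mask.sum(axis=axes, keepdims=True)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        a.accumulate(mask * g)

    return _node(out if keepdims else out.squeeze(axis=axes), (a,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t.accumulate(g[tuple(idx)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def broadcast_hw(a: Tensor, h: int, w: int) -> Tensor:
    """Tile an N×C×1×1 tensor to N×C×H×W (image-pooling branch upsample)."""
    n, c = a.shape[:2]

    def backward(g):
        a.accumulate(g.sum(axis=(2, 3), keepdims=True))

    return _node(np.broadcast_to(a.data, (n, c, h, w)).copy(), (a,), backward)


# -- convolution -------------------------------------------------------------

def _corr2d(x: np.ndarray, w: np.ndarray, dilation: int, pad: int) -> tuple[np.ndarray, np.ndarray]:
    """Stride-1 cross-correlation in NCHW. Returns (output, im2col matrix).

    ``w`` has shape (Cout, Cin, k, k).  Output spatial size is
    H + 2*pad - dilation*(k-1).
    """
    n, cin, h, wdt = x.shape
    cout, _, k, _ = w.shape
    span = dilation * (k - 1) + 1
    if h + 2 * pad < span or wdt + 2 * pad < span:
        raise ValueError(
            f"dilated kernel span {span} exceeds padded input "
            f"{h + 2 * pad}x{wdt + 2 * pad}; reduce the dilation rate"
        )
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (span, span), axis=(2, 3))
    if dilation > 1:
        win = win[..., ::dilation, ::dilation]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * k * k)
    out = cols @ w.reshape(cout, -1).T
    return out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2), cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, dilation: int = 1, pad: int | None = None) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) with optional dilation.

    ``pad=None`` means "same" padding ``dilation*(k-1)//2`` (odd kernels).
    """
    cout, cin, k, _ = w.shape
    if pad is None:
        pad = dilation * (k - 1) // 2
    out, cols = _corr2d(x.data, w.data, dilation, pad)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)

    def backward(g):
        n, _, ho, wo = g.shape
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        if w.requires_grad or w._parents:
            w.accumulate((gmat.T @ cols).reshape(w.shape))
        if b is not None and (b.requires_grad or b._parents):
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            # transpose trick: dL/dx = g (*) rot180(w) with in/out swapped
            wt = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gpad = dilation * (k - 1) - pad
            dx, _ = _corr2d(g, np.ascontiguousarray(wt), dilation, gpad)
            x.accumulate(dx)

    return _node(out, (x, w) if b is None else (x, w, b), backward)


# -- pooling and resampling --------------------------------------------------

def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = win.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        dx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x.accumulate(dx)

    return _node(out, (x,), backward)


_BILINEAR_CACHE: dict[int, tuple] = {}


def _bilinear_coeffs(size: int):
    """Source indices/weights for 2x bilinear upsampling (half-pixel centers)."""
    if size not in _BILINEAR_CACHE:
        src = (np.arange(2 * size) + 0.5) / 2.0 - 0.5
        i0 = np.clip(np.floor(src).astype(int), 0, size - 1)
        i1 = np.clip(i0 + 1, 0, size - 1)
        t = np.clip(src - np.floor(src), 0.0, 1.0)
        t[src < 0] = 0.0
        _BILINEAR_CACHE[size] = (i0, i1, t.astype(DTYPE))
    return _BILINEAR_CACHE[size]


def upsample_bilinear2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    i0, i1, ti = _bilinear_coeffs(h)
    j0, j1, tj = _bilinear_coeffs(w)
    rows = x.data[:, :, i0, :] * (1 - ti)[None, None, :, None] + x.data[:, :, i1, :] * ti[None, None, :, None]
    out = rows[:, :, :, j0] * (1 - tj)[None, None, None, :] + rows[:, :, :, j1] * tj[None, None, None, :]

    def backward(g):
        grows = np.zeros((n, c, 2 * h, w), dtype=DTYPE)
        np.add.at(grows, (slice(None), slice(None), slice(None), j0), g * (1 - tj)[None, None, None, :])
        np.add.at(grows, (slice(None), slice(None), slice(None), j1), g * tj[None, None, None, :])
        dx = np.zeros((n, c, h, w), dtype=DTYPE)
        np.add.at(dx, (slice(None), slice(None), i0, slice(None)), grows * (1 - ti)[None, None, :, None])
        np.add.at(dx, (slice(None), slice(None), i1, slice(None)), grows * ti[None, None, :, None])
        x.accumulate(dx)

    return _node(out, (x,), backward)
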