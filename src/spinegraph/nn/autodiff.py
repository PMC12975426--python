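"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package trains small encoder--decoder segmentation networks on CPU; the
operator set here is exactly what those networks need: nD convolution
(im2col, stride 1 or 2), instance normalization, nearest-neighbour
upsampling, channel concatenation, matrix products for graph layers, ReLU,
and channel softmax.  Everything runs in float32 unless the caller supplies
float64 data.

A :class:`Tensor` wraps an array plus an optional gradient; ops build a DAG
and ``backward()`` walks it in reverse topological order.
"""

from __future__ import annotations

import numpy as np


def _tune_allocator() -> None:
    # Activation buffers exceed glibc's default mmap threshold, so every
    # iteration would otherwise re-fault freshly mapped pages; raising the
    # thresholds keeps the buffers on the heap for reuse.
    try:
        import ctypes
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except Exception:  # pragma: no cover - non-glibc platforms
        pass


_tune_allocator()

__all__ = [
    "Tensor",
    "add",
    "concat",
    "conv",
    "instance_norm",
    "matmul",
    "narrow",
    "relu",
    "reshape",
    "softmax_channels",
    "upsample_nearest",
]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def accumulate(self, g) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this node (gradient seeded with ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"


def _result(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(g)
        if b.requires_grad:
            b.accumulate(g)

    return _result(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0)

    def backward(g):
        x.accumulate(g * mask)

    return _result(out_data, (x,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)

    return _result(out_data, (a, b), backward)


def reshape(x: Tensor, shape) -> Tensor:
    old_shape = x.data.shape
    out_data = x.data.reshape(shape)

    def backward(g):
        x.accumulate(g.reshape(old_shape))

    return _result(out_data, (x,), backward)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    out_data = x.data[sl]

    def backward(g):
        full = np.zeros_like(x.data)
        full[sl] = g
        x.accumulate(full)

    return _result(out_data, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate(g[tuple(sl)])

    return _result(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# Convolution (dimension-generic, offset-accumulation based)
# ---------------------------------------------------------------------------
#
# A k^nd convolution is computed as a sum over kernel offsets of small
# (Cout, Cin) x (Cin, V) matrix products on shifted views of the padded
# input.  This keeps every memory access pattern simple (strided slice +
# GEMM) and needs no column matrix; the same slices serve the weight and
# input gradients.


def _offset_slices(kshape, stride, out_spatial):
    for off in np.ndindex(*kshape):
        yield off, tuple(
            slice(o, o + (n - 1) * s + 1, s)
            for o, n, s in zip(off, out_spatial, stride))


def _im2col(xp: np.ndarray, kshape, stride, out_spatial):
    """Columns ordered (N, K*Cin, V): row block oi*Cin..(oi+1)*Cin is the
    input shifted by kernel offset oi."""
    n, cin = xp.shape[:2]
    nk = int(np.prod(kshape))
    nvox = int(np.prod(out_spatial))
    cols = np.empty((n, nk * cin, nvox), dtype=xp.dtype)
    for oi, (_, sl) in enumerate(_offset_slices(kshape, stride, out_spatial)):
        cols[:, oi * cin:(oi + 1) * cin] = \
            xp[(slice(None), slice(None)) + sl].reshape(n, cin, nvox)
    return cols


def _permute_w(w: np.ndarray):
    """(Cout, Cin, *K) -> (Cout, K*Cin) matching the _im2col row order."""
    nd = w.ndim - 2
    perm = (0,) + tuple(range(2, 2 + nd)) + (1,)
    return np.ascontiguousarray(w.transpose(perm)).reshape(w.shape[0], -1)


def _conv_forward(x: np.ndarray, w: np.ndarray, b, stride, pad):
    nd = w.ndim - 2
    kshape = w.shape[2:]
    xp = np.pad(x, [(0, 0), (0, 0)] + [(p, p) for p in pad]) if any(pad) else x
    n = x.shape[0]
    cout = w.shape[0]
    out_spatial = tuple((xp.shape[2 + i] - kshape[i]) // stride[i] + 1
                        for i in range(nd))
    cols = _im2col(xp, kshape, stride, out_spatial)
    y = _permute_w(w) @ cols  # (N, Cout, V) via broadcasting over N
    if b is not None:
        y += b[:, None].astype(x.dtype)
    return y.reshape(n, cout, *out_spatial), cols, out_spatial


def conv(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, pad=None) -> Tensor:
    """nD cross-correlation; ``w`` has shape (Cout, Cin, *K).

    ``pad`` defaults to "same" padding k//2 per axis; ``stride`` may be an
    int or per-axis tuple.
    """
    nd = w.ndim - 2
    if isinstance(stride, int):
        stride = (stride,) * nd
    if pad is None:
        pad = tuple(k // 2 for k in w.shape[2:])
    elif isinstance(pad, int):
        pad = (pad,) * nd
    if x.data.shape[1] != w.data.shape[1]:
        raise ValueError(
            f"conv channel mismatch: input has {x.data.shape[1]}, "
            f"kernel expects {w.data.shape[1]}")
    bias = b.data if b is not None else None
    out_data, cols, out_spatial = _conv_forward(x.data, w.data, bias, stride, pad)
    kshape = w.data.shape[2:]
    n, cin = x.data.shape[:2]
    cout = w.data.shape[0]
    nvox = int(np.prod(out_spatial))

    def backward(g):
        g2 = np.ascontiguousarray(g.reshape(n, cout, nvox))
        if b is not None and b.requires_grad:
            b.accumulate(g2.sum(axis=(0, 2)))
        if w.requires_grad:
            dw = np.einsum("ncv,nkv->ck", g2, cols, optimize=True) if n > 1 \
                else g2[0] @ cols[0].T  # (Cout, K*Cin)
            dw = dw.reshape((cout,) + kshape + (cin,))
            nd_ = len(kshape)
            dw = dw.transpose((0, nd_ + 1) + tuple(range(1, nd_ + 1)))
            w.accumulate(np.ascontiguousarray(dw))
        if x.requires_grad:
            wpt = np.ascontiguousarray(_permute_w(w.data).T)
            dcols = wpt @ g2  # (N, K*Cin, V)
            spatial = x.data.shape[2:]
            dxp = np.zeros(
                x.data.shape[:2] + tuple(s + 2 * p for s, p in zip(spatial, pad)),
                dtype=g.dtype)
            for oi, (_, sl) in enumerate(_offset_slices(kshape, stride, out_spatial)):
                view = dxp[(slice(None), slice(None)) + sl]
                view += dcols[:, oi * cin:(oi + 1) * cin].reshape(view.shape)
            if any(pad):
                crop = (slice(None), slice(None)) + tuple(
                    slice(p, p + s) for p, s in zip(pad, spatial))
                dxp = dxp[crop]
            x.accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _result(out_data, parents, backward)


# ---------------------------------------------------------------------------
# Normalization / resampling
# ---------------------------------------------------------------------------

def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over spatial axes."""
    axes = tuple(range(2, x.ndim))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    cdim = (1, -1) + (1,) * (x.ndim - 2)
    out_data = xhat * gamma.data.reshape(cdim) + beta.data.reshape(cdim)

    def backward(g):
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0,) + axes).reshape(beta.data.shape))
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(0,) + axes).reshape(gamma.data.shape))
        if x.requires_grad:
            gg = g * gamma.data.reshape(cdim)
            m1 = gg.mean(axis=axes, keepdims=True)
            m2 = (gg * xhat).mean(axis=axes, keepdims=True)
            x.accumulate(inv * (gg - m1 - xhat * m2))

    return _result(out_data, (x, gamma, beta), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of every spatial axis by ``factor``."""
    nd = x.ndim - 2
    shape = x.data.shape
    interleaved = sum(((s, 1) for s in shape[2:]), ())
    broadcast = sum(((s, factor) for s in shape[2:]), ())
    out_data = np.ascontiguousarray(np.broadcast_to(
        x.data.reshape(shape[:2] + interleaved), shape[:2] + broadcast)
    ).reshape(shape[:2] + tuple(s * factor for s in shape[2:]))

    def backward(g):
        # sum-pool the gradient back: exact adjoint of repeat
        shape = []
        for i, s in enumerate(x.data.shape):
            if i < 2:
                shape.append(s)
            else:
                shape.extend([s, factor])
        gr = g.reshape(shape)
        axes = tuple(3 + 2 * i for i in range(nd))
        x.accumulate(gr.sum(axis=axes))

    return _result(out_data, (x,), backward)


def softmax_channels(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        x.accumulate(p * (g - dot))

    return _result(p, (x,), backward)
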