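"""A small reverse-mode automatic differentiation engine on numpy arrays.

The engine covers exactly the operations the volumetric segmentation
network needs: padded/strided 3D convolution (im2col + BLAS matmul, chunked
to bound memory), elementwise arithmetic with broadcasting, ReLU/sigmoid,
channel concatenation, global average pooling, separable trilinear
upsampling, a softmax-weighted scalar gather (for learnable scale weights),
dropout, and a fused weighted softmax cross-entropy loss.

All arrays are float32.  Graphs are built eagerly; ``Tensor.backward()``
runs a topological sweep.  Everything is deterministic given the numpy
seeds supplied by the caller.
"""

from __future__ import annotations

import numpy as np

_COL_BYTES = 96 * 1024 * 1024  # im2col chunk budget


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
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

    # operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward, requires_grad=None) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents) \
        if requires_grad is None else requires_grad
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum-reduce a gradient over axes that were broadcast in the forward."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # split by sign so the exponential never overflows
    x = a.data
    s = np.empty_like(x)
    pos = x >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    s[~pos] = ex / (1.0 + ex)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, o0, o1 in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(o0, o1)
                t._accumulate(g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def mean_all(a: Tensor) -> Tensor:
    n = a.data.size

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.full_like(a.data, float(g) / n))

    return _make(np.float32(a.data.mean()), (a,), backward)


# ---------------------------------------------------------------------------
# pooling / upsampling
# ---------------------------------------------------------------------------

def global_avg_pool(a: Tensor) -> Tensor:
    """(C, D, H, W) -> (C, 1, 1, 1)."""
    n = int(np.prod(a.data.shape[1:]))
    out = a.data.mean(axis=(1, 2, 3), keepdims=True)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g / n, a.data.shape))

    return _make(out, (a,), backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1D linear interpolation operator (half-pixel convention)."""
    A = np.zeros((n_out, n_in), dtype=np.float32)
    f = n_out / n_in
    src = (np.arange(n_out) + 0.5) / f - 0.5
    i0 = np.floor(src).astype(int)
    w = (src - i0).astype(np.float32)
    lo = np.clip(i0, 0, n_in - 1)
    hi = np.clip(i0 + 1, 0, n_in - 1)
    A[np.arange(n_out), lo] += 1.0 - w
    A[np.arange(n_out), hi] += w
    return A


def _apply_axis(x: np.ndarray, A: np.ndarray, axis: int) -> np.ndarray:
    y = np.tensordot(A, x, axes=([1], [axis]))   # (n_out, ...)
    return np.moveaxis(y, 0, axis)


def upsample_trilinear(a: Tensor, out_spatial: tuple[int, int, int]) -> Tensor:
    """Separable trilinear resize of (C, D, H, W) to (C, *out_spatial)."""
    mats = [_interp_matrix(o, i) for o, i in zip(out_spatial, a.data.shape[1:])]
    y = a.data
    for ax, A in enumerate(mats):
        y = _apply_axis(y, A, ax + 1)

    def backward(g):
        if a.requires_grad:
            gx = g
            for ax, A in enumerate(mats):
                gx = _apply_axis(gx, A.T, ax + 1)
            a._accumulate(gx)

    return _make(np.ascontiguousarray(y), (a,), backward)


# ---------------------------------------------------------------------------
# softmax-weighted scalar gather
# ---------------------------------------------------------------------------

def softmax_weight(w: Tensor, idx: int) -> Tensor:
    """Scalar tensor = softmax(w)[idx] for a 1D parameter vector ``w``."""
    e = np.exp(w.data - w.data.max())
    s = e / e.sum()

    def backward(g):
        if w.requires_grad:
            grad = -s[idx] * s
            grad[idx] += s[idx]
            w._accumulate(float(g) * grad)

    return _make(np.float32(s[idx]), (w,), backward)


def dropout(a: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return a
    keep = (rng.random(a.data.shape) >= rate).astype(np.float32) / (1.0 - rate)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * keep)

    return _make(a.data * keep, (a,), backward)


# ---------------------------------------------------------------------------
# 3D convolution
#
# Four execution strategies behind one ``conv3d`` surface, chosen by kernel
# size and stride:
#   * k=1              -> plain channel-mixing GEMM;
#   * stride 1, k=3    -> 27 shifted GEMMs on the flat padded volume
#                         (zero-copy: BLAS handles the strided views);
#   * stride 1, k>=5   -> FFT convolution (used by the multi-scale density
#                         stem, where Cin=1 and kernels are large);
#   * stride 2         -> chunked im2col + GEMM (columns are small because
#                         the output grid is subsampled).
# All paths produce the same same-padded cross-correlation.
# ---------------------------------------------------------------------------

def _out_dim(n: int, k: int, p: int, s: int) -> int:
    return (n + 2 * p - k) // s + 1


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    """Same-padded 3D convolution (cross-correlation convention).

    ``x``: (Cin, D, H, W); ``w``: (Cout, Cin, k, k, k); ``b``: (Cout,) or
    None.  Padding is k//2 on every face, so stride 1 preserves the spatial
    shape and stride 2 halves it.
    """
    Cin, D, H, W = x.data.shape
    Cout, Cin_w, k, _, _ = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"conv3d channel mismatch: input {Cin}, weight {Cin_w}")
    if stride == 1 and k == 1:
        return _conv_1x1(x, w, b)
    if stride == 1 and k == 3:
        return _conv_shifted(x, w, b)
    if stride == 1 and k >= 5:
        return _conv_fft(x, w, b)
    return _conv_im2col(x, w, b, stride)


def _finish(y, b, x, w, backward):
    if b is not None:
        y += b.data[:, None, None, None]
    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, backward)


def _bias_grad(b, g):
    if b is not None and b.requires_grad:
        b._accumulate(g.sum(axis=(1, 2, 3)))


def _conv_1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    Cin, D, H, W = x.data.shape
    Cout = w.data.shape[0]
    x2 = x.data.reshape(Cin, -1)
    W2 = w.data.reshape(Cout, Cin)
    y = (W2 @ x2).reshape(Cout, D, H, W)

    def backward(g):
        _bias_grad(b, g)
        g2 = g.reshape(Cout, -1)
        if w.requires_grad:
            w._accumulate((g2 @ x2.T).reshape(w.data.shape))
        if x.requires_grad:
            x._accumulate((W2.T @ g2).reshape(x.data.shape))

    return _finish(y, b, x, w, backward)


def _conv_shifted(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Stride-1 3x3x3 convolution as 27 shifted GEMM accumulations."""
    Cin, D, H, W = x.data.shape
    Cout = w.data.shape[0]
    Dp, Hp, Wp = D + 2, H + 2, W + 2
    M = Dp * Hp * Wp
    xp = np.zeros((Cin, Dp, Hp, Wp), dtype=np.float32)
    xp[:, 1:1 + D, 1:1 + H, 1:1 + W] = x.data
    x2 = xp.reshape(Cin, M)
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                offsets.append(((dz + 1, dy + 1, dx + 1), (dz * Hp + dy) * Wp + dx))
    y2 = np.zeros((Cout, M), dtype=np.float32)
    for (dz, dy, dx), delta in offsets:
        s0, e0 = max(0, -delta), M - max(0, delta)
        y2[:, s0:e0] += w.data[:, :, dz, dy, dx] @ x2[:, s0 + delta:e0 + delta]
    y = y2.reshape(Cout, Dp, Hp, Wp)[:, 1:1 + D, 1:1 + H, 1:1 + W].copy()

    def backward(g):
        _bias_grad(b, g)
        g2 = np.zeros((Cout, Dp, Hp, Wp), dtype=np.float32)
        g2[:, 1:1 + D, 1:1 + H, 1:1 + W] = g
        g2 = g2.reshape(Cout, M)
        if w.requires_grad:
            dW = np.empty_like(w.data)
            for (dz, dy, dx), delta in offsets:
                s0, e0 = max(0, -delta), M - max(0, delta)
                dW[:, :, dz, dy, dx] = g2[:, s0:e0] @ x2[:, s0 + delta:e0 + delta].T
            w._accumulate(dW)
        if x.requires_grad:
            dxp = np.zeros((Cin, M), dtype=np.float32)
            for (dz, dy, dx), delta in offsets:
                s0, e0 = max(0, -delta), M - max(0, delta)
                dxp[:, s0 + delta:e0 + delta] += w.data[:, :, dz, dy, dx].T @ g2[:, s0:e0]
            x._accumulate(dxp.reshape(Cin, Dp, Hp, Wp)[:, 1:1 + D, 1:1 + H, 1:1 + W])

    return _finish(y, b, x, w, backward)


def _conv_fft(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Stride-1 convolution for large kernels via FFT."""
    from scipy import fft as sfft

    Cin, D, H, W = x.data.shape
    Cout, _, k, _, _ = w.data.shape
    p = k // 2
    nfft = tuple(sfft.next_fast_len(n + k - 1) for n in (D, H, W))
    Xf = sfft.rfftn(x.data, s=nfft, axes=(1, 2, 3))
    Wf = sfft.rfftn(w.data[:, :, ::-1, ::-1, ::-1], s=nfft, axes=(2, 3, 4))
    Yf = np.einsum("oi...,i...->o...", Wf, Xf)
    off = k - 1 - p
    y = sfft.irfftn(Yf, s=nfft, axes=(1, 2, 3))[
        :, off:off + D, off:off + H, off:off + W].astype(np.float32).copy()

    def backward(g):
        _bias_grad(b, g)
        Gf = sfft.rfftn(g, s=nfft, axes=(1, 2, 3))
        if x.requires_grad:
            Wnf = sfft.rfftn(w.data, s=nfft, axes=(2, 3, 4))
            dXf = np.einsum("oi...,o...->i...", Wnf, Gf)
            dx = sfft.irfftn(dXf, s=nfft, axes=(1, 2, 3))[
                :, p:p + D, p:p + H, p:p + W]
            x._accumulate(dx.astype(np.float32))
        if w.requires_grad:
            Pf = np.conj(Xf)[None, :] * Gf[:, None]
            z = sfft.irfftn(Pf, s=nfft, axes=(2, 3, 4))
            idx = [(p - np.arange(k)) % n for n in nfft]
            dW = z[:, :, idx[0]][:, :, :, idx[1]][:, :, :, :, idx[2]]
            w._accumulate(dW.astype(np.float32))

    return _finish(y, b, x, w, backward)


def _col_chunk(xp, k, s, i0, i1, Ho, Wo):
    """im2col for output rows [i0, i1): (Cin*k^3, (i1-i0)*Ho*Wo)."""
    Cin = xp.shape[0]
    n = i1 - i0
    col = np.empty((Cin, k, k, k, n, Ho, Wo), dtype=np.float32)
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                col[:, dz, dy, dx] = xp[
                    :,
                    i0 * s + dz:i0 * s + dz + s * n:s,
                    dy:dy + s * Ho:s,
                    dx:dx + s * Wo:s,
                ]
    return col.reshape(Cin * k ** 3, n * Ho * Wo)


def _conv_im2col(x: Tensor, w: Tensor, b: Tensor | None, stride: int) -> Tensor:
    Cin, D, H, W = x.data.shape
    Cout, _, k, _, _ = w.data.shape
    p, s = k // 2, stride
    Do, Ho, Wo = (_out_dim(n, k, p, s) for n in (D, H, W))
    xp = np.zeros((Cin, D + 2 * p, H + 2 * p, W + 2 * p), dtype=np.float32)
    if p:
        xp[:, p:p + D, p:p + H, p:p + W] = x.data
    else:
        xp = x.data
    W2 = w.data.reshape(Cout, -1)
    rows = Cin * k ** 3
    chunk = max(1, min(Do, int(_COL_BYTES / 4 / max(1, rows * Ho * Wo))))
    y = np.empty((Cout, Do, Ho, Wo), dtype=np.float32)
    for i0 in range(0, Do, chunk):
        i1 = min(i0 + chunk, Do)
        col = _col_chunk(xp, k, s, i0, i1, Ho, Wo)
        y[:, i0:i1] = (W2 @ col).reshape(Cout, i1 - i0, Ho, Wo)

    def backward(g):
        _bias_grad(b, g)
        need_dx = x.requires_grad
        need_dw = w.requires_grad
        dxp = np.zeros_like(xp) if need_dx else None
        dW2 = np.zeros_like(W2) if need_dw else None
        for i0 in range(0, Do, chunk):
            i1 = min(i0 + chunk, Do)
            gc = g[:, i0:i1].reshape(Cout, -1)
            if need_dw:
                col = _col_chunk(xp, k, s, i0, i1, Ho, Wo)
                dW2 += gc @ col.T
            if need_dx:
                dcol = (W2.T @ gc).reshape(Cin, k, k, k, i1 - i0, Ho, Wo)
                n = i1 - i0
                for dz in range(k):
                    for dy in range(k):
                        for dx_ in range(k):
                            dxp[:,
                                i0 * s + dz:i0 * s + dz + s * n:s,
                                dy:dy + s * Ho:s,
                                dx_:dx_ + s * Wo:s] += dcol[:, dz, dy, dx_]
        if need_dw:
            w._accumulate(dW2.reshape(w.data.shape))
        if need_dx:
            x._accumulate(dxp[:, p:p + D, p:p + H, p:p + W] if p else dxp)

    return _finish(y, b, x, w, backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def weighted_ce(logits: Tensor, labels: np.ndarray, class_weights: np.ndarray) -> Tensor:
    """Weighted softmax cross-entropy, mean over all samples (voxels).

    ``logits``: (K, *spatial); ``labels``: integer array of shape *spatial*;
    ``class_weights``: (K,).  Matches the standard multi-class weighted
    cross-entropy: -1/N sum_n w_{y_n} log softmax(x_n)_{y_n}.
    """
    K = logits.data.shape[0]
    flat = logits.data.reshape(K, -1)
    y = np.asarray(labels).reshape(-1)
    if y.min() < 0 or y.max() >= K:
        raise ValueError(f"labels must lie in [0, {K}), got range [{y.min()}, {y.max()}]")
    w = np.asarray(class_weights, dtype=np.float64)
    if w.shape != (K,):
        raise ValueError(f"class_weights must have shape ({K},)")
    N = y.size
    m = flat.max(axis=0)
    ex = np.exp(flat - m)
    logZ = np.log(ex.sum(axis=0)) + m
    nll = logZ - flat[y, np.arange(N)]
    loss = np.float64((w[y] * nll).mean())

    def backward(g):
        if logits.requires_grad:
            p = ex / ex.sum(axis=0)
            p *= w[y][None, :].astype(np.float32)
            p[y, np.arange(N)] -= w[y].astype(np.float32)
            logits._accumulate((float(g) / N) * p.reshape(logits.data.shape))

    return _make(np.float32(loss), (logits,), backward)
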