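"""Minimal reverse-mode autodiff on NumPy arrays.

Supports exactly the operations the detection, registration and
classification networks need: dense/conv layers, pooling, upsampling,
concatenation, pointwise nonlinearities, bilinear warping of an image by a
displacement field, and a handful of fused losses.  Everything is float32
by default and fully deterministic (no threading, no atomics).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() only on scalar tensors")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def pow_const(self, p: float):
        out = _node(self.data ** p, (self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def exp(self):
        out = _node(np.exp(self.data), (self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def clamp(self, lo: float, hi: float):
        out = _node(np.clip(self.data, lo, hi), (self,))
        mask = ((self.data > lo) & (self.data < hi)).astype(DTYPE)
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def abs(self):
        out = _node(np.abs(self.data), (self,))
        out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    # -- reductions / shape ------------------------------------------------

    def sum(self):
        out = _node(self.data.sum(keepdims=False), (self,))
        out._backward = lambda g: self._accumulate(
            np.broadcast_to(g, self.data.shape))
        return out

    def mean(self):
        n = self.data.size
        out = _node(self.data.mean(), (self,))
        out._backward = lambda g: self._accumulate(
            np.broadcast_to(g / n, self.data.shape))
        return out

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = _node(np.ascontiguousarray(self.data.transpose(axes)), (self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        out = _node(np.maximum(self.data, 0.0), (self,))
        mask = (self.data > 0).astype(DTYPE)
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def leaky_relu(self, alpha: float = 0.2):
        slope = np.where(self.data > 0, 1.0, alpha).astype(DTYPE)
        out = _node(self.data * slope, (self,))
        out._backward = lambda g: self._accumulate(g * slope)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(s, (self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    # -- linear algebra ----------------------------------------------------

    def matmul(self, other: "Tensor"):
        out = _node(self.data @ other.data, (self, other))

        def bwd(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents) -> Tensor:
    t = Tensor(data)
    t._parents = tuple(parents)
    return t


def _unbroadcast(g, shape):
    """Sum gradient g down to the given broadcast-source shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# structured ops
# ---------------------------------------------------------------------------


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = _node(np.concatenate(datas, axis=axis), tensors)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """NCHW convolution (cross-correlation) via sliding windows."""
    N, C, H, W = x.data.shape
    O, Ci, kh, kw = w.data.shape
    assert Ci == C, f"channel mismatch {Ci} != {C}"
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
    y = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)
    if b is not None:
        y = y + b.data.reshape(1, O, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = _node(y, parents)

    def bwd(g):
        w._accumulate(np.einsum("nohw,nchwij->ocij", g, win, optimize=True))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            dcols = np.einsum("nohw,ocij->nchwij", g, w.data, optimize=True)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * Ho : stride,
                        j : j + stride * Wo : stride] += dcols[:, :, :, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    out._backward = bwd
    return out


def max_pool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    assert H % 2 == 0 and W % 2 == 0, "max_pool2x2 needs even spatial dims"
    r = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    y = r.max(axis=(3, 5))
    out = _node(y, (x,))

    def bwd(g):
        mask = (r == y[:, :, :, None, :, None]).astype(DTYPE)
        mask /= mask.sum(axis=(3, 5), keepdims=True)  # split ties evenly
        gx = (mask * g[:, :, :, None, :, None]).reshape(N, C, H, W)
        x._accumulate(gx)

    out._backward = bwd
    return out


def avg_pool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    assert H % 2 == 0 and W % 2 == 0
    r = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    out = _node(r.mean(axis=(3, 5)), (x,))

    def bwd(g):
        gx = np.broadcast_to(
            g[:, :, :, None, :, None] / 4.0, r.shape).reshape(N, C, H, W)
        x._accumulate(gx)

    out._backward = bwd
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    N, C, H, W = x.data.shape
    out = _node(x.data.mean(axis=(2, 3)), (x,))

    def bwd(g):
        x._accumulate(
            np.broadcast_to(g[:, :, None, None] / (H * W), x.data.shape))

    out._backward = bwd
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = _node(y, (x,))

    def bwd(g):
        N, C, H2, W2 = g.shape
        gx = g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
        x._accumulate(gx)

    out._backward = bwd
    return out


def warp_bilinear(img: Tensor, field: Tensor) -> Tensor:
    """Pull-back warp: out[n, c, p] = img[n, c, p + field[n, :, p]].

    ``field`` has shape (N, 2, H, W) — row then column displacement.
    Samples are clamped to the image (replicate border).  Differentiable in
    both arguments.
    """
    N, C, H, W = img.data.shape
    rows = np.arange(H, dtype=DTYPE)[None, :, None]
    cols = np.arange(W, dtype=DTYPE)[None, None, :]
    sr = np.clip(rows + field.data[:, 0], 0.0, H - 1.0)  # (N, H, W)
    sc = np.clip(cols + field.data[:, 1], 0.0, W - 1.0)
    inside_r = (rows + field.data[:, 0] > 0) & (rows + field.data[:, 0] < H - 1)
    inside_c = (cols + field.data[:, 1] > 0) & (cols + field.data[:, 1] < W - 1)
    r0 = np.floor(sr).astype(np.int64)
    c0 = np.floor(sc).astype(np.int64)
    r1 = np.minimum(r0 + 1, H - 1)
    c1 = np.minimum(c0 + 1, W - 1)
    fr = (sr - r0).astype(DTYPE)
    fc = (sc - c0).astype(DTYPE)
    ni = np.arange(N)[:, None, None]
    I = img.data  # (N, C, H, W)

    def gather(rr, cc):
        return I[ni[:, None], np.arange(C)[None, :, None, None],
                 rr[:, None], cc[:, None]]  # (N, C, H, W)

    v00, v01 = gather(r0, c0), gather(r0, c1)
    v10, v11 = gather(r1, c0), gather(r1, c1)
    frb = fr[:, None]
    fcb = fc[:, None]
    y = ((1 - frb) * (1 - fcb) * v00 + (1 - frb) * fcb * v01
         + frb * (1 - fcb) * v10 + frb * fcb * v11)
    out = _node(y, (img, field))

    def bwd(g):
        if field.requires_grad or field._parents:
            d_dr = ((v10 - v00) * (1 - fcb) + (v11 - v01) * fcb)
            d_dc = ((v01 - v00) * (1 - frb) + (v11 - v10) * frb)
            gr = (g * d_dr).sum(axis=1) * inside_r
            gc = (g * d_dc).sum(axis=1) * inside_c
            field._accumulate(np.stack([gr, gc], axis=1))
        if img.requires_grad or img._parents:
            gimg = np.zeros_like(I)
            for rr, cc, wgt in ((r0, c0, (1 - frb) * (1 - fcb)),
                                (r0, c1, (1 - frb) * fcb),
                                (r1, c0, frb * (1 - fcb)),
                                (r1, c1, frb * fcb)):
                flat = rr[:, None] * W + cc[:, None]  # (N, 1, H, W)
                flat = np.broadcast_to(flat, (N, C, H, W)).reshape(N * C, -1)
                vals = (g * wgt).reshape(N * C, -1)
                tgt = gimg.reshape(N * C, -1)
                for k in range(N * C):
                    np.add.at(tgt[k], flat[k], vals[k])
            img._accumulate(gimg)

    out._backward = bwd
    return out


def field_smoothness(field: Tensor) -> Tensor:
    """Mean squared forward difference of a (N, 2, H, W) field."""
    f = field.data
    dr = f[:, :, 1:, :] - f[:, :, :-1, :]
    dc = f[:, :, :, 1:] - f[:, :, :, :-1]
    val = (dr ** 2).mean() + (dc ** 2).mean()
    out = _node(np.asarray(val, dtype=DTYPE), (field,))

    def bwd(g):
        gf = np.zeros_like(f)
        gf[:, :, 1:, :] += 2 * dr * (g / dr.size)
        gf[:, :, :-1, :] -= 2 * dr * (g / dr.size)
        gf[:, :, :, 1:] += 2 * dc * (g / dc.size)
        gf[:, :, :, :-1] -= 2 * dc * (g / dc.size)
        field._accumulate(gf)

    out._backward = bwd
    return out


def local_ncc_loss(warped: Tensor, fixed: np.ndarray, radius: int = 3,
                   eps: float = 1e-5) -> Tensor:
    """Negative mean windowed squared correlation (VoxelMorph-style CC).

    ``fixed`` is plain data; gradient flows into ``warped`` only.  Windows
    are uniform (2r+1)^2 boxes computed with box filters.
    """
    from scipy.ndimage import uniform_filter

    m = warped.data.astype(np.float64)
    f = np.asarray(fixed, dtype=np.float64)
    assert m.shape == f.shape
    size = [0] * m.ndim
    size[-2] = size[-1] = 2 * radius + 1

    def box(a):
        return uniform_filter(a, size=size, mode="reflect")

    mu_m, mu_f = box(m), box(f)
    mm = box(m * m) - mu_m ** 2
    ff = box(f * f) - mu_f ** 2
    mf = box(m * f) - mu_m * mu_f
    cc = mf ** 2 / (mm * ff + eps)
    out = _node(np.asarray(-cc.mean(), dtype=DTYPE), (warped,))

    def bwd(g):
        n = cc.size
        # d(-mean cc)/dm via window-level coefficient maps redistributed
        # with a second box filter (adjoint of the first).
        A = 2 * mf / (mm * ff + eps)           # coefficient of (f - mu_f)
        B = mf ** 2 / (mm * ff + eps) ** 2 * ff  # coefficient of (m - mu_m)
        t1 = box(A) * f - box(A * mu_f)
        t2 = 2 * (box(B) * m - box(B * mu_m))
        grad = -(t1 - t2) / n * float(g)
        warped._accumulate(grad.astype(DTYPE))

    out._backward = bwd
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weights: np.ndarray | None = None) -> Tensor:
    """Numerically stable elementwise binary cross-entropy, mean-reduced."""
    z = logits.data.astype(np.float64)
    t = np.asarray(targets, dtype=np.float64)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if weights is not None:
        loss = loss * weights
    out = _node(np.asarray(loss.mean(), dtype=DTYPE), (logits,))

    def bwd(g):
        p = 1.0 / (1.0 + np.exp(-z))
        grad = (p - t)
        if weights is not None:
            grad = grad * weights
        logits._accumulate((grad / z.size * float(g)).astype(DTYPE))

    out._backward = bwd
    return out
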