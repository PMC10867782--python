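"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the primitives the translation networks need:
elementwise arithmetic, reductions, matrix products, 2-D (transposed,
depthwise, deformable) convolutions and the usual nonlinearities.  Arrays are
kept in float64 NCHW layout.  Every differentiable primitive registers a
closure that accumulates gradients into its parents; ``Tensor.backward`` runs
the closures in reverse topological order.

Gradient correctness of every nontrivial primitive is pinned by central
finite-difference checks in the test-suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "deform_conv2d",
    "depthwise_conv2d",
    "pad2d",
    "reflect_pad2d",
    "softplus",
    "where_mask",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
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
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free graph references eagerly
            node._backward = None
            node._parents = ()

    # -- construction helper ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward, requires_grad=None):
        out = Tensor(data)
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in parents)
        out.requires_grad = requires_grad
        if requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- elementwise arithmetic ---------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._make(data, (self,), backward)

    def abs(self):
        data = np.abs(self.data)
        sign = np.sign(self.data)

        def backward(g):
            self._accum(g * sign)

        return Tensor._make(data, (self,), backward)

    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            self._accum(g * data)

        return Tensor._make(data, (self,), backward)

    def log(self):
        data = np.log(self.data)

        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(data, (self,), backward)

    def tanh(self):
        data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - data * data))

        return Tensor._make(data, (self,), backward)

    def sigmoid(self):
        data = _sigmoid(self.data)

        def backward(g):
            self._accum(g * data * (1.0 - data))

        return Tensor._make(data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        data = np.where(mask, self.data, 0.0)

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(data, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        data = np.where(mask, self.data, slope * self.data)

        def backward(g):
            self._accum(g * np.where(mask, 1.0, slope))

        return Tensor._make(data, (self,), backward)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, tuple(a % self.ndim for a in ax))
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = np.expand_dims(data, axis) if not keepdims else data
        mask = (self.data == expanded).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(g * mask)

        return Tensor._make(data, (self,), backward)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(data, (self,), backward)

    def transpose(self, axes):
        data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(data, (self,), backward)

    def __getitem__(self, key):
        data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return Tensor._make(data, (self,), backward)

    def matmul(self, other: "Tensor"):
        other = as_tensor(other)
        data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(data, (self, other), backward)

    __matmul__ = matmul


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + e^x), computed without overflow; d/dx = sigmoid(x)."""
    x = as_tensor(x)
    data = np.logaddexp(0.0, x.data)
    sig = _sigmoid(x.data)

    def backward(g):
        x._accum(g * sig)

    return Tensor._make(data, (x,), backward)


def where_mask(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select a where mask else b; mask is a constant boolean array."""
    a, b = as_tensor(a), as_tensor(b)
    data = np.where(mask, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(np.where(mask, g, 0.0), a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.where(mask, 0.0, g), b.shape))

    return Tensor._make(data, (a, b), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), backward)


def pad2d(x: Tensor, pad: tuple[int, int, int, int]) -> Tensor:
    """Zero-pad an NCHW tensor by (top, bottom, left, right)."""
    t, b, l, r = pad
    x = as_tensor(x)
    data = np.pad(x.data, ((0, 0), (0, 0), (t, b), (l, r)))
    H, W = x.shape[2], x.shape[3]

    def backward(g):
        x._accum(g[:, :, t:t + H, l:l + W])

    return Tensor._make(data, (x,), backward)


def _reflect_indices(n: int, pad: int) -> np.ndarray:
    idx = np.arange(-pad, n + pad)
    # half-sample symmetric reflection (scipy.ndimage "reflect" mode)
    idx = np.where(idx < 0, -1 - idx, idx)
    idx = np.where(idx >= n, 2 * n - 1 - idx, idx)
    return idx


def reflect_pad2d(x: Tensor, pad: int) -> Tensor:
    x = as_tensor(x)
    ri = _reflect_indices(x.shape[2], pad)
    ci = _reflect_indices(x.shape[3], pad)
    data = x.data[:, :, ri][:, :, :, ci]

    def backward(g):
        full = np.zeros_like(x.data)
        np.add.at(full, (slice(None), slice(None), ri[:, None], ci[None, :]), g)
        x._accum(full)

    return Tensor._make(data, (x,), backward)


# -- convolutions -----------------------------------------------------------

def _sliding(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> strided view (N,C,Ho,Wo,kh,kw)."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """Cross-correlation with zero padding; w is (Cout, Cin, kh, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    Cout, Cin, kh, kw = w.shape
    if x.shape[1] != Cin:
        raise ValueError(f"conv2d channel mismatch: {x.shape[1]} vs {Cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = _sliding(xp, kh, kw, stride)
    data = np.einsum("nchwij,ocij->nohw", cols, w.data, optimize=True)
    if b is not None:
        data = data + b.data[None, :, None, None]
    N, _, Ho, Wo = data.shape
    H, W = x.shape[2], x.shape[3]

    def backward(g):
        if w.requires_grad:
            w._accum(np.einsum("nchwij,nohw->ocij", cols, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                        np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
            x._accum(gxp[:, :, pad:pad + H, pad:pad + W])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(data, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2, pad: int = 1) -> Tensor:
    """Transposed convolution; w is (Cin, Cout, kh, kw).

    Output size is (H-1)*stride - 2*pad + k; with k=4, stride=2, pad=1 this
    exactly doubles the resolution.
    """
    x, w = as_tensor(x), as_tensor(w)
    Cin, Cout, kh, kw = w.shape
    N, _, H, W = x.shape
    Hf, Wf = (H - 1) * stride + kh, (W - 1) * stride + kw
    full = np.zeros((N, Cout, Hf, Wf))
    for i in range(kh):
        for j in range(kw):
            full[:, :, i:i + stride * (H - 1) + 1:stride,
                 j:j + stride * (W - 1) + 1:stride] += \
                np.einsum("nchw,co->nohw", x.data, w.data[:, :, i, j], optimize=True)
    data = full[:, :, pad:Hf - pad, pad:Wf - pad]
    if b is not None:
        data = data + b.data[None, :, None, None]

    def backward(g):
        gfull = np.pad(g, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        gw = np.zeros_like(w.data) if w.requires_grad else None
        gx = np.zeros_like(x.data) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                sl = gfull[:, :, i:i + stride * (H - 1) + 1:stride,
                           j:j + stride * (W - 1) + 1:stride]
                if gw is not None:
                    gw[:, :, i, j] += np.einsum("nchw,nohw->co", x.data, sl,
                                                optimize=True)
                if gx is not None:
                    gx += np.einsum("nohw,co->nchw", sl, w.data[:, :, i, j],
                                    optimize=True)
        if gw is not None:
            w._accum(gw)
        if gx is not None:
            x._accum(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(data, parents, backward)


def depthwise_conv2d(x: Tensor, kernel: np.ndarray, reflect: bool = True) -> Tensor:
    """Convolve every channel with the same (kh,kw) constant kernel.

    Used for the differentiable Gaussian blur; reflect padding keeps the
    image mean invariant under a normalized kernel.
    """
    x = as_tensor(x)
    kh, kw = kernel.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("depthwise kernel size must be odd")
    p = kh // 2
    xp = reflect_pad2d(x, p) if reflect else pad2d(x, (p, p, p, p))
    cols = _sliding(xp.data, kh, kw, 1)
    data = np.einsum("nchwij,ij->nchw", cols, kernel, optimize=True)
    H, W = x.shape[2], x.shape[3]

    def backward(g):
        gxp = np.zeros_like(xp.data)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + H, j:j + W] += g * kernel[i, j]
        xp._accum(gxp)

    out = Tensor._make(data, (xp,), backward)
    return out


def deform_conv2d(x: Tensor, offsets: Tensor, w: Tensor, b: Tensor | None = None,
                  stride: int = 1, pad: int = 0) -> Tensor:
    """Deformable convolution: kernel taps displaced by learned offsets.

    ``offsets`` has 2*kh*kw channels, ordered (dy, dx) per tap, at the output
    resolution.  Samples are taken by bilinear interpolation with zeros
    outside the (zero-padded) input; the op is differentiable in the input,
    the offsets and the weights.
    """
    x, offsets, w = as_tensor(x), as_tensor(offsets), as_tensor(w)
    Cout, Cin, kh, kw = w.shape
    K = kh * kw
    N, C, H, W = x.shape
    if C != Cin:
        raise ValueError(f"deform_conv2d channel mismatch: {C} vs {Cin}")
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    if offsets.shape != (N, 2 * K, Ho, Wo):
        raise ValueError(
            f"offset field shape {offsets.shape} != {(N, 2 * K, Ho, Wo)}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = xp.shape[2], xp.shape[3]

    off = offsets.data.reshape(N, K, 2, Ho, Wo)
    ti, tj = np.divmod(np.arange(K), kw)                       # tap grid
    base_y = (np.arange(Ho) * stride)[None, :, None] + ti[:, None, None]
    base_x = (np.arange(Wo) * stride)[None, None, :] + tj[:, None, None]
    py = base_y[None] + off[:, :, 0]                           # (N,K,Ho,Wo)
    px = base_x[None] + off[:, :, 1]

    y0 = np.floor(py).astype(np.int64)
    x0 = np.floor(px).astype(np.int64)
    wy = py - y0
    wx = px - x0

    def gather(yi, xi):
        valid = (yi >= 0) & (yi < Hp) & (xi >= 0) & (xi < Wp)
        yc = np.clip(yi, 0, Hp - 1)
        xc = np.clip(xi, 0, Wp - 1)
        # (N,C,K,Ho,Wo)
        n_idx = np.arange(N)[:, None, None, None]
        vals = xp[n_idx[:, None], np.arange(C)[None, :, None, None, None],
                  yc[:, None], xc[:, None]]
        return vals * valid[:, None], valid, yc, xc

    v00, m00, y00, x00 = gather(y0, x0)
    v01, m01, y01, x01 = gather(y0, x0 + 1)
    v10, m10, y10, x10 = gather(y0 + 1, x0)
    v11, m11, y11, x11 = gather(y0 + 1, x0 + 1)

    wy_, wx_ = wy[:, None], wx[:, None]
    sampled = (v00 * (1 - wy_) * (1 - wx_) + v01 * (1 - wy_) * wx_
               + v10 * wy_ * (1 - wx_) + v11 * wy_ * wx_)      # (N,C,K,Ho,Wo)

    wk = w.data.reshape(Cout, Cin, K)
    data = np.einsum("nckhw,ock->nohw", sampled, wk, optimize=True)
    if b is not None:
        data = data + b.data[None, :, None, None]

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("nckhw,nohw->ock", sampled, g, optimize=True)
            w._accum(gw.reshape(w.shape))
        if not (x.requires_grad or offsets.requires_grad):
            return
        gs = np.einsum("nohw,ock->nckhw", g, wk, optimize=True)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            flat = gxp.reshape(N * C, Hp * Wp)
            for (vv, mm, yy, xx, ww) in (
                (v00, m00, y00, x00, (1 - wy_) * (1 - wx_)),
                (v01, m01, y01, x01, (1 - wy_) * wx_),
                (v10, m10, y10, x10, wy_ * (1 - wx_)),
                (v11, m11, y11, x11, wy_ * wx_),
            ):
                contrib = gs * ww * mm[:, None]
                lin = (yy * Wp + xx)[:, None]                  # (N,1,K,Ho,Wo)
                lin = np.broadcast_to(lin, (N, C, K, Ho, Wo))
                rows = np.broadcast_to(
                    np.arange(N * C).reshape(N, C, 1, 1, 1), lin.shape)
                np.add.at(flat, (rows.ravel(), lin.ravel()), contrib.ravel())
            x._accum(gxp[:, :, pad:pad + H, pad:pad + W])
        if offsets.requires_grad:
            # d(sampled)/dpy and /dpx from the bilinear weights
            dval_dy = ((v10 - v00) * (1 - wx_) + (v11 - v01) * wx_)
            dval_dx = ((v01 - v00) * (1 - wy_) + (v11 - v10) * wy_)
            gy = (gs * dval_dy).sum(axis=1)                    # (N,K,Ho,Wo)
            gx = (gs * dval_dx).sum(axis=1)
            goff = np.stack([gy, gx], axis=2).reshape(N, 2 * K, Ho, Wo)
            offsets._accum(goff)

    parents = [x, offsets, w] + ([b] if b is not None else [])
    return Tensor._make(data, tuple(parents), backward)
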