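"""Minimal reverse-mode automatic differentiation over numpy arrays.

A ``Tensor`` wraps a float32 numpy array and records the operations applied
to it; ``Tensor.backward()`` runs the reverse sweep in topological order.
Only the operations the W-shaped network needs are provided: elementwise
arithmetic, batched matmul, activations, reductions, reshaping, 2-D
convolution / transposed convolution (im2col based, row-chunked to bound
memory), pooling, nearest upsampling, concatenation, dropout and softmax.

Convolution layouts follow the NCHW convention.
"""

from __future__ import annotations

import numpy as np

_COL_BYTES_BUDGET = 256 * 1024 * 1024  # chunk im2col buffers to ~256 MB

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = _GRAD_ENABLED[-1] and any(
            p.requires_grad for p in parents
        )
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float32)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            if t._parents == ():  # leaf
                t.grad = g if t.grad is None else t.grad + g
        # the root may itself be a leaf
        if self._parents == () and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float32)

    # -- basic arithmetic --------------------------------------------------
    def _coerce(self, other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            ),
        )
        return out

    def __pow__(self, p):
        assert np.isscalar(p)
        out = Tensor._make(
            self.data**p,
            (self,),
            lambda g: (g * p * self.data ** (p - 1),),
        )
        return out

    def matmul(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data

        def backward(g):
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(np.matmul(a, b), (self, other), backward)

    __matmul__ = matmul

    # -- activations -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, alpha: float = 0.01):
        mask = self.data > 0
        scale = np.where(mask, 1.0, alpha).astype(np.float32)
        return Tensor._make(self.data * scale, (self,), lambda g: (g * scale,))

    def sigmoid(self):
        x = self.data
        s = np.empty_like(x)
        pos = x >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        s[~pos] = ex / (1.0 + ex)
        return Tensor._make(s, (self,), lambda g: (g * s * (1 - s),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor._make(e, (self,), lambda g: (g * e,))

    def log(self, eps: float = 1e-12):
        clamped = np.maximum(self.data, eps)
        return Tensor._make(
            np.log(clamped), (self,), lambda g: (g / clamped * (self.data >= eps),)
        )

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(
                    g, axis if isinstance(axis, int) else tuple(sorted(axis))
                )
            return (np.broadcast_to(g, self.data.shape).astype(np.float32),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        def backward(g):
            out = np.zeros_like(self.data)
            out[idx] = g
            return (out,)

        return Tensor._make(self.data[idx], (self,), backward)

    def softmax(self, axis: int = -1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        e = np.exp(x - m)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return ((g - dot) * y,)

        return Tensor._make(y, (self,), backward)

    def log_softmax(self, axis: int = -1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        ls = x - m - np.log(np.exp(x - m).sum(axis=axis, keepdims=True))
        sm = np.exp(ls)

        def backward(g):
            return (g - sm * g.sum(axis=axis, keepdims=True),)

        return Tensor._make(ls, (self,), backward)

    def item(self) -> float:
        return float(self.data)

    @property
    def shape(self):
        return self.data.shape

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool = True) -> Tensor:
    if not train or p <= 0:
        return x
    mask = (rng.uniform(size=x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    return Tensor._make(x.data * mask, (x,), lambda g: (g * mask,))


# ---------------------------------------------------------------------------
# convolution primitives (numpy-level helpers, then Tensor ops)


def _row_block(C, kh, kw, out_w, n, itemsize=4):
    rows = max(1, _COL_BYTES_BUDGET // max(1, n * C * kh * kw * out_w * itemsize))
    return rows


def _conv2d_fwd(x, w, stride, pad):
    N, C, H, W = x.shape
    O, _, kh, kw = w.shape
    out_h = (H + 2 * pad - kh) // stride + 1
    out_w = (W + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    w2 = w.reshape(O, -1)
    out = np.empty((N, O, out_h, out_w), dtype=np.float32)
    block = _row_block(C, kh, kw, out_w, N)
    for r0 in range(0, out_h, block):
        r1 = min(out_h, r0 + block)
        rows = r1 - r0
        cols = np.empty((N, C, kh, kw, rows, out_w), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = xp[
                    :, :, i + r0 * stride : i + r1 * stride : stride,
                    j : j + out_w * stride : stride,
                ][:, :, :rows]
        cols = cols.reshape(N, C * kh * kw, rows * out_w)
        out[:, :, r0:r1, :] = np.matmul(w2, cols).reshape(N, O, rows, out_w)
    return out


def _conv2d_bwd_input(dout, w, x_shape, stride, pad):
    N, O, out_h, out_w = dout.shape
    _, C, kh, kw = w.shape
    H, W = x_shape[2], x_shape[3]
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=np.float32)
    w2 = w.reshape(O, -1)
    block = _row_block(C, kh, kw, out_w, N)
    for r0 in range(0, out_h, block):
        r1 = min(out_h, r0 + block)
        rows = r1 - r0
        dcols = np.matmul(
            w2.T, dout[:, :, r0:r1, :].reshape(N, O, rows * out_w)
        ).reshape(N, C, kh, kw, rows, out_w)
        for i in range(kh):
            for j in range(kw):
                dxp[
                    :, :, i + r0 * stride : i + r1 * stride : stride,
                    j : j + out_w * stride : stride,
                ][:, :, :rows] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def _conv2d_bwd_weight(x, dout, w_shape, stride, pad):
    N, C, H, W = x.shape
    O, _, kh, kw = w_shape
    out_h, out_w = dout.shape[2], dout.shape[3]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    dw = np.zeros((O, C * kh * kw), dtype=np.float32)
    block = _row_block(C, kh, kw, out_w, N)
    for r0 in range(0, out_h, block):
        r1 = min(out_h, r0 + block)
        rows = r1 - r0
        cols = np.empty((N, C, kh, kw, rows, out_w), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = xp[
                    :, :, i + r0 * stride : i + r1 * stride : stride,
                    j : j + out_w * stride : stride,
                ][:, :, :rows]
        cols = cols.reshape(N, C * kh * kw, rows * out_w)
        d = dout[:, :, r0:r1, :].reshape(N, O, rows * out_w)
        dw += np.einsum("nol,ncl->oc", d, cols, optimize=True)
    return dw.reshape(w_shape)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution, NCHW; ``w`` is (out, in, kh, kw)."""
    out_data = _conv2d_fwd(x.data, w.data, stride, pad)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    def backward(g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        dx = _conv2d_bwd_input(g, w.data, x.data.shape, stride, pad)
        dw = _conv2d_bwd_weight(x.data, g, w.data.shape, stride, pad)
        db = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor._make(out_data, parents, backward)


def conv_transpose2d(
    x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2, pad: int = 1
) -> Tensor:
    """Transposed convolution; ``w`` is (in, out, kh, kw).

    With kernel 4, stride 2, pad 1 the spatial size exactly doubles.
    """
    N, Cin, H, W = x.data.shape
    _, Cout, kh, kw = w.data.shape
    out_h = (H - 1) * stride - 2 * pad + kh
    out_w = (W - 1) * stride - 2 * pad + kw
    out_data = _conv2d_bwd_input(
        x.data, w.data, (N, Cout, out_h, out_w), stride, pad
    )
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    def backward(g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        dx = _conv2d_fwd(g, w.data, stride, pad)
        dw = _conv2d_bwd_weight(g, x.data, w.data.shape, stride, pad)
        db = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor._make(out_data, parents, backward)


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k max pooling with stride k, ceil mode (edge-padded with -inf)."""
    N, C, H, W = x.data.shape
    ph = (-H) % k
    pw = (-W) % k
    xp = x.data
    if ph or pw:
        xp = np.pad(
            xp, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf
        )
    oh, ow = xp.shape[2] // k, xp.shape[3] // k
    windows = xp.reshape(N, C, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, C, oh, ow, k * k
    )
    idx = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dwin = np.zeros_like(windows)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dxp = dwin.reshape(N, C, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(
            N, C, oh * k, ow * k
        )
        return (dxp[:, :, :H, :W],)

    return Tensor._make(out_data, (x,), backward)


def avgpool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k average pooling with stride k (ceil mode, zero-padded)."""
    N, C, H, W = x.data.shape
    ph = (-H) % k
    pw = (-W) % k
    xp = x.data
    if ph or pw:
        xp = np.pad(xp, ((0, 0), (0, 0), (0, ph), (0, pw)))
    oh, ow = xp.shape[2] // k, xp.shape[3] // k
    out_data = xp.reshape(N, C, oh, k, ow, k).mean(axis=(3, 5))

    def backward(g):
        dxp = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        return (dxp[:, :, :H, :W].astype(np.float32),)

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    out_data = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)
    N, C, H, W = x.data.shape

    def backward(g):
        return (
            g.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5)).astype(np.float32),
        )

    return Tensor._make(out_data, (x,), backward)


def crop_or_pad(x: Tensor, h: int, w: int) -> Tensor:
    """Center-crop or zero-pad the spatial dims to (h, w)."""
    N, C, H, W = x.data.shape
    if H == h and W == w:
        return x
    # crop first
    r0 = max((H - h) // 2, 0)
    c0 = max((W - w) // 2, 0)
    cropped_h = min(H, h)
    cropped_w = min(W, w)
    ph0 = max((h - H) // 2, 0)
    pw0 = max((w - W) // 2, 0)
    out_data = np.zeros((N, C, h, w), dtype=np.float32)
    out_data[:, :, ph0 : ph0 + cropped_h, pw0 : pw0 + cropped_w] = x.data[
        :, :, r0 : r0 + cropped_h, c0 : c0 + cropped_w
    ]

    def backward(g):
        dx = np.zeros_like(x.data)
        dx[:, :, r0 : r0 + cropped_h, c0 : c0 + cropped_w] = g[
            :, :, ph0 : ph0 + cropped_h, pw0 : pw0 + cropped_w
        ]
        return (dx,)

    return Tensor._make(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))
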