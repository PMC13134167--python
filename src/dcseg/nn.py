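"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains small convolutional encoder--decoder networks on CPU, so
the engine only implements the operations those networks need: 3x3 / 1x1
convolution (stride 1), window pooling with stride equal to the window,
bilinear or nearest resizing, channel-wise softmax, dropout, concatenation,
elementwise arithmetic and reductions.  Everything is float32.

All arrays follow the NCHW layout (batch, channels, height, width).
Gradients are accumulated by a tape walk in reverse topological order;
there is no graph reuse — each forward pass builds a fresh tape.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "as_tensor", "relu", "concat", "softmax", "log", "exp",
    "clip_min", "conv2d", "avg_pool2d", "max_pool2d", "resize2d",
    "dropout", "SGD",
]


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data, dtype=np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- operators ------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: (g * b.data, g * a.data))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: (g / b.data,
                                        -g * a.data / (b.data * b.data)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return self * -1.0

    def __pow__(self, p):
        if p != 2:
            raise NotImplementedError("only squaring is supported")
        return self * self

    def sum(self, axis=None, keepdims=False):
        out = _node(np.sum(self.data, axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            shape = self.data.shape

            def bw(g):
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accumulate(np.broadcast_to(gg, shape).astype(np.float32))

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            orig = self.data.shape
            out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    out._parents = tuple(p for p in parents if p.requires_grad)
    return out


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _binary(a, b, fwd, grads) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _node(fwd(a.data, b.data), (a, b))
    if out.requires_grad:
        def bw(g):
            ga, gb = grads(g, a, b)
            if a.requires_grad:
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(gb, b.data.shape))
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _node(np.maximum(x.data, 0.0), (x,))
    if out.requires_grad:
        mask = x.data > 0
        out._backward = lambda g: x._accumulate(g * mask)
    return out


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _node(np.exp(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * out.data)
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _node(np.log(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g / x.data)
    return out


def clip_min(x: Tensor, lo: float) -> Tensor:
    """Clamp from below; gradient passes only where the input exceeds ``lo``."""
    x = as_tensor(x)
    out = _node(np.maximum(x.data, lo), (x,))
    if out.requires_grad:
        mask = x.data > lo
        out._backward = lambda g: x._accumulate(g * mask)
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _node(y, (x,))
    if out.requires_grad:
        def bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))
        out._backward = bw
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, gi in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(gi)
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# spatial operations
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), stride 1, NCHW layout.

    ``w`` has shape (C_out, C_in, kh, kw).
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.data.shape
    cout, cin, kh, kw = w.data.shape
    if cin != c:
        raise ValueError(f"channel mismatch: input {c}, kernel expects {cin}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho, wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))          # n,c,ho,wo,kh,kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                ).reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(cout, c * kh * kw)
    out_d = cols @ wmat.T
    if b is not None:
        b = as_tensor(b)
        out_d = out_d + b.data
    out_d = out_d.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = _node(np.ascontiguousarray(out_d), parents)
    if out.requires_grad:
        def bw(g):
            gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)
                                      ).reshape(n * ho * wo, cout)
            if w.requires_grad:
                w._accumulate((gm.T @ cols).reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accumulate(gm.sum(axis=0))
            if x.requires_grad:
                dcols = (gm @ wmat).reshape(n, ho, wo, c, kh, kw)
                dxp = np.zeros_like(xp)
                for ki in range(kh):
                    for kj in range(kw):
                        dxp[:, :, ki:ki + ho, kj:kj + wo] += \
                            dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
                x._accumulate(dxp[:, :, p:p + h, p:p + wd] if p else dxp)
        out._backward = bw
    return out


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Average pooling with window ``k`` and stride ``k``.

    A trailing remainder that does not fill a window is cropped away; the
    caller is expected to resize back if the original geometry is needed.
    """
    x = as_tensor(x)
    if k == 1:
        return x
    n, c, h, w = x.data.shape
    ho, wo = h // k, w // k
    if ho < 1 or wo < 1:
        raise ValueError(f"input {h}x{w} smaller than pooling window {k}")
    xc = x.data[:, :, :ho * k, :wo * k]
    out = _node(xc.reshape(n, c, ho, k, wo, k).mean(axis=(3, 5)), (x,))
    if out.requires_grad:
        def bw(g):
            dx = np.zeros_like(x.data)
            dx[:, :, :ho * k, :wo * k] = np.repeat(
                np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            x._accumulate(dx)
        out._backward = bw
    return out


def max_pool2d(x: Tensor, k: int) -> Tensor:
    """Max pooling, window = stride = ``k``; remainder cropped."""
    x = as_tensor(x)
    if k == 1:
        return x
    n, c, h, w = x.data.shape
    ho, wo = h // k, w // k
    if ho < 1 or wo < 1:
        raise ValueError(f"input {h}x{w} smaller than pooling window {k}")
    win = x.data[:, :, :ho * k, :wo * k].reshape(n, c, ho, k, wo, k)
    win = win.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, k * k)
    idx = win.argmax(axis=-1)
    out = _node(np.take_along_axis(win, idx[..., None], axis=-1)[..., 0], (x,))
    if out.requires_grad:
        def bw(g):
            dwin = np.zeros((n, c, ho, wo, k * k), dtype=np.float32)
            np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
            dwin = dwin.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
            dx = np.zeros_like(x.data)
            dx[:, :, :ho * k, :wo * k] = dwin.reshape(n, c, ho * k, wo * k)
            x._accumulate(dx)
        out._backward = bw
    return out


def _interp_matrix(n_in: int, n_out: int, mode: str) -> np.ndarray:
    """Dense (n_out, n_in) interpolation matrix, align_corners=False."""
    a = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        s = (o + 0.5) * scale - 0.5
        if mode == "nearest":
            a[o, min(n_in - 1, max(0, int(np.floor((o + 0.5) * scale))))] = 1.0
            continue
        s0 = int(np.floor(s))
        t = s - s0
        i0 = min(max(s0, 0), n_in - 1)
        i1 = min(max(s0 + 1, 0), n_in - 1)
        a[o, i0] += 1.0 - t
        a[o, i1] += t
    return a


def resize2d(x: Tensor, out_h: int, out_w: int, mode: str = "bilinear") -> Tensor:
    """Resize NCHW features to (out_h, out_w); bilinear is align_corners=False."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if (h, w) == (out_h, out_w):
        return x
    ah = _interp_matrix(h, out_h, mode)
    aw = _interp_matrix(w, out_w, mode)
    # out[n,c,o,p] = sum_{h,w} ah[o,h] x[n,c,h,w] aw[p,w]
    tmp = np.einsum("oh,nchw->ncow", ah, x.data, optimize=True)
    out = _node(np.einsum("pw,ncow->ncop", aw, tmp, optimize=True), (x,))
    if out.requires_grad:
        def bw(g):
            t2 = np.einsum("pw,ncop->ncow", aw, g, optimize=True)
            x._accumulate(np.einsum("oh,ncow->nchw", ah, t2, optimize=True))
        out._backward = bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            train: bool) -> Tensor:
    """Inverted dropout; identity when ``train`` is False or rate is 0."""
    x = as_tensor(x)
    if not train or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(np.float32) / keep
    out = _node(x.data * mask, (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * mask)
    return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay.

    v <- momentum * v + grad + weight_decay * w ;  w <- w - lr * v
    """

    def __init__(self, params: dict[str, Tensor], lr: float,
                 momentum: float = 0.9, weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v = self.velocity[k]
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
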