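"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains its separation/reconstruction networks with this small
tensor engine: a :class:`Tensor` wraps a float64 ``numpy`` array and records
the operations that produced it, so a scalar loss can be backpropagated
through convolutions, batch normalisation, the frequency-domain filter of the
FBP network and the SSIM loss.  Only the primitives the models need are
implemented; every primitive's gradient is finite-difference checked in the
test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "matmul",
    "relu",
    "sigmoid",
    "sqrt",
    "square",
    "sum_axes",
    "mean_axes",
    "reshape",
    "narrow",
    "concat",
    "max_pool_global",
    "avg_pool_global",
    "conv2d",
    "fourier_filter",
    "backproject",
    "backward",
]


class Tensor:
    """A numpy array with an optional gradient and autodiff history."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        backward(self)

    # operator sugar
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __rsub__(self, other):
        return sub(as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# graph plumbing
# ---------------------------------------------------------------------------

def _make(data, parents, backward_fn) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` to ``shape`` by summing over broadcast axes."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def backward(t: Tensor) -> None:
    """Backpropagate from a scalar (or any) tensor through the graph."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(t, False)]
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
    t.grad = np.ones_like(t.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
            if node is not t:
                # free intermediate grads/graph as we go
                node._backward = None


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(a.data - b.data, (a, b), bw)


def neg(a: Tensor) -> Tensor:
    def bw(g):
        _accum(a, -g)

    return _make(-a.data, (a,), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), bw)


def div(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data**2), b.data.shape))

    return _make(a.data / b.data, (a, b), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _make(a.data @ b.data, (a, b), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        _accum(a, g * s * (1.0 - s))

    return _make(s, (a,), bw)


def sqrt(a: Tensor) -> Tensor:
    r = np.sqrt(a.data)

    def bw(g):
        _accum(a, g * 0.5 / r)

    return _make(r, (a,), bw)


def square(a: Tensor) -> Tensor:
    def bw(g):
        _accum(a, 2.0 * g * a.data)

    return _make(a.data**2, (a,), bw)


def sum_axes(a: Tensor, axes=None, keepdims: bool = False) -> Tensor:
    axes_t = tuple(range(a.ndim)) if axes is None else (
        (axes,) if isinstance(axes, int) else tuple(axes)
    )

    def bw(g):
        gg = g
        if not keepdims:
            for ax in sorted(axes_t):
                gg = np.expand_dims(gg, ax)
        _accum(a, np.broadcast_to(gg, a.data.shape))

    return _make(a.data.sum(axis=axes_t, keepdims=keepdims), (a,), bw)


def mean_axes(a: Tensor, axes=None, keepdims: bool = False) -> Tensor:
    axes_t = tuple(range(a.ndim)) if axes is None else (
        (axes,) if isinstance(axes, int) else tuple(axes)
    )
    count = int(np.prod([a.data.shape[i] for i in axes_t]))
    return mul(sum_axes(a, axes_t, keepdims), Tensor(1.0 / count))


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape

    def bw(g):
        _accum(a, g.reshape(old))

    return _make(a.data.reshape(shape), (a,), bw)


def narrow(a: Tensor, axis: int, start: int, stop: int) -> Tensor:
    sl = [slice(None)] * a.ndim
    sl[axis] = slice(start, stop)
    sl = tuple(sl)

    def bw(g):
        full = np.zeros_like(a.data)
        full[sl] = g
        _accum(a, full)

    return _make(a.data[sl], (a,), bw)


def concat(tensors, axis: int) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(lo), int(hi))
            _accum(t, g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def max_pool_global(a: Tensor) -> Tensor:
    """Global max over the two spatial axes of an NCHW tensor -> (N, C, 1, 1)."""
    m = a.data.max(axis=(2, 3), keepdims=True)
    mask = (a.data == m)
    counts = mask.sum(axis=(2, 3), keepdims=True)

    def bw(g):
        _accum(a, g * mask / counts)

    return _make(m, (a,), bw)


def avg_pool_global(a: Tensor) -> Tensor:
    """Global average over the two spatial axes of an NCHW tensor -> (N, C, 1, 1)."""
    return mean_axes(a, (2, 3), keepdims=True)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def same_padding(k: int) -> tuple[int, int]:
    """Asymmetric zero padding preserving length for stride-1 kernels.

    Even kernels (the global H x 1 / 1 x W branches) pad one pixel more on
    the trailing side.
    """
    lo = (k - 1) // 2
    return lo, k - 1 - lo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad="same") -> Tensor:
    """2-D cross-correlation, stride 1.

    x: (N, Ci, H, W); w: (Co, Ci, kh, kw); b: (Co,) or None.
    ``pad`` is "same" or ((pt, pb), (pl, pr)).
    """
    N, Ci, H, W = x.data.shape
    Co, Ci2, kh, kw = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"conv2d channel mismatch: input {Ci}, weight {Ci2}")
    if pad == "same":
        (pt, pb), (pl, pr) = same_padding(kh), same_padding(kw)
    else:
        (pt, pb), (pl, pr) = pad
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    Ho = H + pt + pb - kh + 1
    Wo = W + pl + pr - kw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("kernel larger than padded input")
    y = np.zeros((N, Co, Ho, Wo))
    for u in range(kh):
        for v in range(kw):
            y += np.einsum(
                "oc,nchw->nohw", w.data[:, :, u, v], xp[:, :, u:u + Ho, v:v + Wo],
                optimize=True,
            )
    if b is not None:
        y += b.data[None, :, None, None]

    def bw(g):
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for u in range(kh):
                for v in range(kw):
                    gw[:, :, u, v] = np.einsum(
                        "nohw,nchw->oc", g, xp[:, :, u:u + Ho, v:v + Wo],
                        optimize=True,
                    )
            _accum(w, gw)
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    gxp[:, :, u:u + Ho, v:v + Wo] += np.einsum(
                        "oc,nohw->nchw", w.data[:, :, u, v], g, optimize=True,
                    )
            _accum(x, gxp[:, :, pt:pt + H, pl:pl + W])

    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, bw)


# ---------------------------------------------------------------------------
# frequency-domain filtering (the learnable FBP filter)
# ---------------------------------------------------------------------------

def fourier_filter(x: Tensor, f: Tensor, pad_len: int) -> Tensor:
    """Filter the radial-bin axis of a (N, C, bins, angles) tensor.

    The signal is zero-padded to ``pad_len`` along the bin axis, multiplied in
    the real-FFT domain by the real filter ``f`` (length ``pad_len // 2 + 1``,
    shared across angles, channels and batch), inverse-transformed and cropped
    back.  With a Hermitian (real, even) spectrum the padded operator is
    self-adjoint, which the backward pass exploits.
    """
    N, C, nb, na = x.data.shape
    P = int(pad_len)
    if f.data.shape != (P // 2 + 1,):
        raise ValueError("filter length must be pad_len//2 + 1")
    xp = np.zeros((N, C, P, na))
    xp[:, :, :nb, :] = x.data
    X = np.fft.rfft(xp, axis=2)
    y = np.fft.irfft(X * f.data[None, None, :, None], n=P, axis=2)[:, :, :nb, :]

    def bw(g):
        gp = np.zeros((N, C, P, na))
        gp[:, :, :nb, :] = g
        G = np.fft.rfft(gp, axis=2)
        if x.requires_grad:
            gx = np.fft.irfft(G * f.data[None, None, :, None], n=P, axis=2)
            _accum(x, gx[:, :, :nb, :])
        if f.requires_grad:
            prod = (X * np.conj(G)).real.sum(axis=(0, 1, 3)) / P
            scale = np.full(P // 2 + 1, 2.0)
            scale[0] = 1.0
            if P % 2 == 0:
                scale[-1] = 1.0
            _accum(f, prod * scale)

    return _make(y, (x, f), bw)


# ---------------------------------------------------------------------------
# fixed linear operators (back-projection)
# ---------------------------------------------------------------------------

def backproject(x: Tensor, B: sp.spmatrix, out_hw: tuple[int, int]) -> Tensor:
    """Apply a fixed sparse back-projection matrix frame-by-frame.

    x: (N, C, bins, angles) -> (N, C, H, W).  ``B`` has shape
    (H*W, bins*angles) and carries no trainable parameters.
    """
    N, C, nb, na = x.data.shape
    H, W = out_hw
    flat = x.data.reshape(N * C, nb * na)
    y = (B @ flat.T).T.reshape(N, C, H, W)

    def bw(g):
        gflat = g.reshape(N * C, H * W)
        gx = (B.T @ gflat.T).T.reshape(N, C, nb, na)
        _accum(x, gx)

    return _make(y, (x,), bw)
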