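"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine records a tape of operations on :class:`Tensor` objects and
back-propagates gradients through a topological sort of the graph.  Only the
operations needed by the segmentation network are implemented: broadcast
arithmetic, matmul, reshape, reductions, ReLU/sigmoid/log/exp, channel
concatenation, stride-1 2-D convolution, 2x2 max pooling and 2x2 stride-2
transposed convolution.  Convolutions are realized as einsum contractions over
sliding windows, which numpy dispatches to BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- basic properties ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ----------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other
        return Tensor._from_op(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._from_op(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        return Tensor._from_op(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._coerce(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        a = self
        out = a.data ** exponent
        return Tensor._from_op(
            out, (a,), lambda g: (g * exponent * a.data ** (exponent - 1.0),)
        )

    __pow__ = pow

    def matmul(self, other):
        other = self._coerce(other)
        a, b = self, other
        return Tensor._from_op(
            a.data @ b.data,
            (a, b),
            lambda g: (g @ b.data.T, a.data.T @ g),
        )

    __matmul__ = matmul

    # -- reductions / shaping -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, a.data.shape).copy(),)

        return Tensor._from_op(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        return Tensor._from_op(
            a.data.reshape(*shape), (a,), lambda g: (g.reshape(a.data.shape),)
        )

    # -- nonlinearities --------------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._from_op(a.data * mask, (a,), lambda g: (g * mask,))

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._from_op(s, (a,), lambda g: (g * s * (1.0 - s),))

    def exp(self):
        a = self
        e = np.exp(a.data)
        return Tensor._from_op(e, (a,), lambda g: (g * e,))

    def log(self):
        a = self
        return Tensor._from_op(np.log(a.data), (a,), lambda g: (g / a.data,))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where un-clamped."""
        a = self
        mask = (a.data >= lo) & (a.data <= hi)
        return Tensor._from_op(np.clip(a.data, lo, hi), (a,), lambda g: (g * mask,))


# ---------------------------------------------------------------------------
# structural / convolutional ops (module-level functions)
# ---------------------------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(np.concatenate(datas, axis=axis), tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: tuple[int, int] = (0, 0)) -> Tensor:
    """Stride-1 cross-correlation of NCHW input with DCkhkw kernels."""
    ph, pw = padding
    kh, kw = w.data.shape[2], w.data.shape[3]
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,H',W',kh,kw
    out = np.einsum("nchwij,dcij->ndhw", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)

    def backward(g):
        gw = np.einsum("nchwij,ndhw->dcij", win, g, optimize=True)
        # full correlation with spatially flipped, channel-transposed kernels
        wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        gp = np.pad(g, ((0, 0), (0, 0), (kh - 1 - ph, kh - 1 - ph),
                        (kw - 1 - pw, kw - 1 - pw)))
        gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
        gx = np.einsum("ndhwij,cdij->nchw", gwin, wf, optimize=True)
        grads = [gx, gw]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._from_op(out, parents, backward)


def max_pool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2x2 requires even spatial dims")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gx.reshape(n, c, h, w),)

    return Tensor._from_op(out, (x,), backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-2 transposed convolution with a 2x2 kernel (doubles H and W).

    Kernel layout is (C_in, C_out, 2, 2), matching the convention that the
    transpose of a conv maps its output channels back to input channels.
    """
    n, c, h, wd = x.data.shape
    out = np.einsum("nchw,cdab->ndhawb", x.data, w.data, optimize=True)
    out = out.reshape(n, w.data.shape[1], 2 * h, 2 * wd)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)

    def backward(g):
        gi = g.reshape(n, w.data.shape[1], h, 2, wd, 2).transpose(0, 1, 2, 4, 3, 5)
        # gi: n,d,h,w,a,b
        gx = np.einsum("ndhwab,cdab->nchw", gi, w.data, optimize=True)
        gw = np.einsum("nchw,ndhwab->cdab", x.data, gi, optimize=True)
        grads = [gx, gw]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._from_op(out, parents, backward)
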