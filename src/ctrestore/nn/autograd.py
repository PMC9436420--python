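"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operator set the restoration networks need:
broadcast arithmetic, reductions, pointwise nonlinearities, channel
concatenation, reflection/zero padding, strided convolution and strided
transposed convolution.  Gradients for the convolutions are computed with
a kernel-position scatter/gather (k*k einsum passes), which is exact and
keeps memory bounded by the activation size.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled", "set_dtype"]

_GRAD_ENABLED = True

#: Engine-wide float dtype.  float32 is the working precision (memory-bound
#: convolutions run ~2x faster); float64 is available for gradient checks.
DTYPE = np.float32


def set_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype).type


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

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
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other
        return Tensor._make(
            a.data + b.data, (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        return Tensor._make(
            a.data * b.data, (a, b),
            lambda g: (_unbroadcast(g * b.data, a.shape),
                       _unbroadcast(g * a.data, b.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other
        return Tensor._make(
            a.data / b.data, (a, b),
            lambda g: (_unbroadcast(g / b.data, a.shape),
                       _unbroadcast(-g * a.data / b.data ** 2, b.shape)))

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        a = self
        return Tensor._make(
            a.data ** p, (a,), lambda g: (g * p * a.data ** (p - 1),))

    def __getitem__(self, idx):
        a = self

        def back(g):
            out = np.zeros_like(a.data)
            out[idx] = g
            return (out,)

        return Tensor._make(a.data[idx], (a,), back)

    # -------------------------------------------------------------- pointwise
    def exp(self):
        a = self
        y = np.exp(a.data)
        return Tensor._make(y, (a,), lambda g: (g * y,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        y = np.sqrt(a.data)
        return Tensor._make(y, (a,), lambda g: (g * 0.5 / y,))

    def abs(self):
        a = self
        return Tensor._make(np.abs(a.data), (a,), lambda g: (g * np.sign(a.data),))

    def sigmoid(self):
        a = self
        y = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(y, (a,), lambda g: (g * y * (1.0 - y),))

    def tanh(self):
        a = self
        y = np.tanh(a.data)
        return Tensor._make(y, (a,), lambda g: (g * (1.0 - y * y),))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def leaky_relu(self, alpha: float = 0.2):
        a = self
        slope = np.where(a.data > 0, 1.0, alpha)
        return Tensor._make(a.data * slope, (a,), lambda g: (g * slope,))

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        a = self

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.shape).copy(),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims=False):
        a = self
        n = a.data.size if axis is None else np.prod(
            [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: (g.reshape(a.shape),))

    # ----------------------------------------------------------------- layout
    def pad2d(self, pad: int, mode: str = "zero"):
        """Pad the last two axes by `pad` on each side ('zero' or 'reflect')."""
        a = self
        if pad == 0:
            return a
        width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
        if mode == "zero":
            y = np.pad(a.data, width)

            def back(g):
                sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
                return (g[sl],)

            return Tensor._make(y, (a,), back)
        if mode == "reflect":
            H, W = a.shape[-2], a.shape[-1]
            idx_h = np.pad(np.arange(H), pad, mode="reflect")
            idx_w = np.pad(np.arange(W), pad, mode="reflect")
            y = a.data[..., idx_h, :][..., :, idx_w]
            flat_idx = (idx_h[:, None] * W + idx_w[None, :]).ravel()

            def back(g):
                lead = g.shape[:-2]
                gx = np.zeros(lead + (H * W,), dtype=g.dtype)
                np.add.at(gx, (Ellipsis, flat_idx), g.reshape(lead + (-1,)))
                return (gx.reshape(a.shape),)

            return Tensor._make(y, (a,), back)
        raise ValueError(f"unknown pad mode {mode!r}")

    # ----------------------------------------------------------- convolutions
    def conv2d(self, w: "Tensor", b: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2-D cross-correlation; x:(N,C,H,W), w:(O,C,kh,kw) -> (N,O,Ho,Wo)."""
        a = self
        O, C, kh, kw = w.shape
        s, p = stride, padding
        xp = np.pad(a.data, [(0, 0), (0, 0), (p, p), (p, p)]) if p else a.data
        Hp, Wp = xp.shape[2], xp.shape[3]
        Ho, Wo = (Hp - kh) // s + 1, (Wp - kw) // s + 1
        N, C = xp.shape[0], xp.shape[1]

        def subs():
            """Contiguous (N, C, Ho*Wo) window slab per kernel position."""
            for i in range(kh):
                for j in range(kw):
                    sub = xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
                    yield i, j, np.ascontiguousarray(sub).reshape(N, C, Ho * Wo)

        y = np.zeros((N, O, Ho * Wo), dtype=xp.dtype)
        for i, j, sub in subs():
            y += np.matmul(w.data[:, :, i, j], sub)
        y = y.reshape(N, O, Ho, Wo)
        if b is not None:
            y = y + b.data[None, :, None, None]

        def back(g):
            g2 = np.ascontiguousarray(g).reshape(N, O, Ho * Wo)
            gw = np.empty_like(w.data)
            gxp = np.zeros_like(xp)
            for i, j, sub in subs():
                gw[:, :, i, j] = np.matmul(g2, sub.transpose(0, 2, 1)).sum(0)
                gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += np.matmul(
                    w.data[:, :, i, j].T, g2).reshape(N, C, Ho, Wo)
            gx = gxp[:, :, p:Hp - p, p:Wp - p] if p else gxp
            gb = g.sum(axis=(0, 2, 3)) if b is not None else None
            return (gx, gw) if b is None else (gx, gw, gb)

        parents = (a, w) if b is None else (a, w, b)
        return Tensor._make(y, parents, back)

    def conv_transpose2d(self, w: "Tensor", b: "Tensor | None" = None,
                         stride: int = 1, padding: int = 0,
                         output_padding: int = 0):
        """Transposed convolution; x:(N,C,H,W), w:(C,O,kh,kw).

        Output side = (H-1)*stride - 2*padding + kh + output_padding.
        """
        a = self
        C, O, kh, kw = w.shape
        s, p, op = stride, padding, output_padding
        N, _, H, W = a.shape
        Hf, Wf = (H - 1) * s + kh + op, (W - 1) * s + kw + op
        x2 = np.ascontiguousarray(a.data).reshape(N, C, H * W)
        yf = np.zeros((N, O, Hf, Wf), dtype=a.data.dtype)
        for i in range(kh):
            for j in range(kw):
                contrib = np.matmul(w.data[:, :, i, j].T, x2).reshape(N, O, H, W)
                yf[:, :, i:i + s * H:s, j:j + s * W:s] += contrib
        y = yf[:, :, p:Hf - p, p:Wf - p] if p else yf
        if b is not None:
            y = y + b.data[None, :, None, None]

        def back(g):
            gf = np.zeros((N, O, Hf, Wf), dtype=g.dtype) if p \
                else np.ascontiguousarray(g)
            if p:
                gf[:, :, p:Hf - p, p:Wf - p] = g
            gx = np.zeros((N, C, H * W), dtype=g.dtype)
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    sub = np.ascontiguousarray(
                        gf[:, :, i:i + s * H:s, j:j + s * W:s]
                    ).reshape(N, O, H * W)
                    gx += np.matmul(w.data[:, :, i, j], sub)
                    gw[:, :, i, j] = np.matmul(x2, sub.transpose(0, 2, 1)).sum(0)
            gb = g.sum(axis=(0, 2, 3)) if b is not None else None
            return (gx.reshape(N, C, H, W), gw) if b is None \
                else (gx.reshape(N, C, H, W), gw, gb)

        parents = (a, w) if b is None else (a, w, b)
        return Tensor._make(y, parents, back)

    # ------------------------------------------------------------- norm layer
    def instance_norm(self, eps: float = 1e-5):
        """Per-sample, per-channel standardization over the spatial axes."""
        mu = self.mean(axis=(2, 3), keepdims=True)
        centered = self - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        return centered / (var + eps).sqrt()


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis` (differentiable)."""
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tuple(tensors), back)
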