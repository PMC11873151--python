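"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result propagates gradients
to every tensor created with ``requires_grad=True``.  The operation set is
exactly what the model zoo needs: broadcasting arithmetic, (batched) matrix
products, im2col-based 2-D convolution, max pooling, bilinear resizing,
reductions, and the usual pointwise nonlinearities.  Float64 throughout —
the networks are desk-scale and exact gradients simplify testing.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "concat", "stack", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (frozen teachers, eval)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and is_grad_enabled()
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()
        self.name = name

    # ---------------------------------------------------------------- basics
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None] | None) -> "Tensor":
        req = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(p for p in parents if p.requires_grad)

            def _bw():
                backward(out.grad)

            out._backward = _bw
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return _as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data ** p, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(np.matmul(self.data, other.data), (self, other),
                          backward)

    # ------------------------------------------------------------- pointwise
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def backward(g):
            self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def gelu(self) -> "Tensor":
        # exact Gaussian-error-function form
        x = self.data
        phi = 0.5 * (1.0 + _erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def backward(g):
            self._accum(g * (phi + x * pdf))

        return self._make(x * phi, (self,), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def var(self, axis=None, keepdims: bool = False) -> "Tensor":
        mu = self.mean(axis=axis, keepdims=True)
        d = self - mu
        return (d * d).mean(axis=axis, keepdims=keepdims)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data)
        mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * gg)

        data = out_data if keepdims else out_data.squeeze(axis)
        return self._make(data, (self,), backward)

    # ---------------------------------------------------------- shape moves
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(self.data[idx], (self,), backward)

    def pad2d(self, pad: int) -> "Tensor":
        """Zero-pad the trailing two (spatial) axes symmetrically."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]

        def backward(g):
            sl = [slice(None)] * (self.ndim - 2) + [slice(pad, -pad)] * 2
            self._accum(g[tuple(sl)])

        return self._make(np.pad(self.data, width), (self,), backward)

    # ------------------------------------------------- structured primitives
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2-D convolution, NCHW input, OIKK weight; im2col + matmul."""
        x = self.pad2d(padding)
        n, c, h, w = x.shape
        co, ci, kh, kw = weight.shape
        if ci != c:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {ci}")
        ho = (h - kh) // stride + 1
        wo = (w - kw) // stride + 1
        # (n, c, kh, kw, ho, wo) patch view via stride tricks
        sn, sc, sh, sw = x.data.strides
        patches = np.lib.stride_tricks.as_strided(
            x.data, (n, c, kh, kw, ho, wo),
            (sn, sc, sh, sw, sh * stride, sw * stride), writeable=False)
        cols = patches.reshape(n, c * kh * kw, ho * wo)
        wmat = weight.data.reshape(co, c * kh * kw)
        out_data = np.matmul(wmat, cols).reshape(n, co, ho, wo)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, co, 1, 1)
        parents = [x, weight] + ([bias] if bias is not None else [])

        def backward(g):
            gmat = g.reshape(n, co, ho * wo)
            if weight.requires_grad:
                gw = np.einsum("nop,ncp->oc", gmat, cols).reshape(weight.shape)
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gcols = np.matmul(wmat.T, gmat)  # (n, c*kh*kw, ho*wo)
                gx = np.zeros((n, c, h, w))
                gp = gcols.reshape(n, c, kh, kw, ho, wo)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i:i + ho * stride:stride,
                           j:j + wo * stride:stride] += gp[:, :, i, j]
                x._accum(gx)

        return x._make(out_data, parents, backward)

    def max_pool2d(self, kernel: int, stride: int | None = None) -> "Tensor":
        stride = stride or kernel
        n, c, h, w = self.shape
        ho = (h - kernel) // stride + 1
        wo = (w - kernel) // stride + 1
        sn, sc, sh, sw = self.data.strides
        patches = np.lib.stride_tricks.as_strided(
            self.data, (n, c, ho, wo, kernel, kernel),
            (sn, sc, sh * stride, sw * stride, sh, sw), writeable=False)
        flat = patches.reshape(n, c, ho, wo, kernel * kernel)
        arg = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            gx = np.zeros_like(self.data)
            ki, kj = np.unravel_index(arg, (kernel, kernel))
            ii = (np.arange(ho)[None, None, :, None] * stride + ki)
            jj = (np.arange(wo)[None, None, None, :] * stride + kj)
            nn = np.arange(n)[:, None, None, None]
            cc = np.arange(c)[None, :, None, None]
            np.add.at(gx, (nn, cc, ii, jj), g)
            self._accum(gx)

        return self._make(out_data, (self,), backward)

    def bilinear_resize(self, out_h: int, out_w: int) -> "Tensor":
        """Bilinear resize of trailing two axes (align_corners=False)."""
        h, w = self.shape[-2], self.shape[-1]
        wh = _interp_matrix(h, out_h)
        ww = _interp_matrix(w, out_w)
        out_data = np.einsum("...hw,hi,wj->...ij", self.data, wh, ww)

        def backward(g):
            self._accum(np.einsum("...ij,hi,wj->...hw", g, wh, ww))

        return self._make(out_data, (self,), backward)

    # --------------------------------------------------------------- engine
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad needs scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_in, n_out) bilinear interpolation weights, align_corners=False."""
    m = np.zeros((n_in, n_out))
    if n_in == 1:
        m[0, :] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    for j in range(n_out):
        m[lo[j], j] += 1.0 - frac[j]
        m[hi[j], j] += frac[j]
    return m


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    sizes = [t.shape[axis] for t in ts]
    offs = np.cumsum([0] + sizes)
    out_data = np.concatenate([t.data for t in ts], axis=axis)

    req = is_grad_enabled() and any(t.requires_grad for t in ts)
    out = Tensor(out_data, requires_grad=req)
    if req:
        out._prev = tuple(t for t in ts if t.requires_grad)

        def _bw():
            for t, a, b in zip(ts, offs[:-1], offs[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out.ndim
                    sl[axis] = slice(a, b)
                    t._accum(out.grad[tuple(sl)])

        out._backward = _bw
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [t.reshape(*t.shape[:axis], 1, *t.shape[axis:]) for t in tensors]
    return concat(ts, axis=axis)
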