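"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations needed by the models in this package:
dense layers, 3x3 strided convolutions and their transposes, the usual
pointwise nonlinearities, and sum reductions. Gradients are accumulated
into ``Tensor.grad`` by :meth:`Tensor.backward`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = tuple(_prev)

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [t]
            while stack:
                node = stack.pop()
                if id(node) in seen:
                    continue
                pending = [p for p in node._prev if id(p) not in seen]
                if pending:
                    stack.append(node)
                    stack.extend(pending)
                else:
                    seen.add(id(node))
                    topo.append(node)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def _make(self, data: np.ndarray, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents), _prev=parents)
        if out.requires_grad:
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __pow__(self, exponent: float):
        assert np.isscalar(exponent)

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return self._make(self.data ** exponent, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # -- reductions / shape ---------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy()
                                 if np.ndim(g) else np.full_like(self.data, g))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g):
            self._accumulate(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return self._make(self.data[idx], (self,), bw)

    # -- pointwise nonlinearities --------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def relu(self):
        def bw(g):
            self._accumulate(g * (self.data > 0))

        return self._make(np.maximum(self.data, 0.0), (self,), bw)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def softplus(self):
        # log(1 + e^x), overflow-safe
        out_data = np.logaddexp(0.0, self.data)

        def bw(g):
            self._accumulate(g * 0.5 * (1.0 + np.tanh(0.5 * self.data)))

        return self._make(out_data, (self,), bw)

    def logsigmoid(self):
        # log sigma(x) = -softplus(-x); numerically stable in both tails
        out_data = -np.logaddexp(0.0, -self.data)

        def bw(g):
            self._accumulate(g * 0.5 * (1.0 - np.tanh(0.5 * self.data)))

        return self._make(out_data, (self,), bw)

    def abs(self):
        def bw(g):
            self._accumulate(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), bw)

    # -- convolutions ---------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 2,
               padding: int = 1):
        """x:(N,C,H,W), weight:(O,C,kh,kw), bias:(O,). Returns (N,O,Ho,Wo)."""
        x, w, b = self, weight, bias
        N, C, H, W = x.data.shape
        O, _, kh, kw = w.data.shape
        Ho = (H + 2 * padding - kh) // stride + 1
        Wo = (W + 2 * padding - kw) // stride + 1
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        out = np.zeros((N, O, Ho, Wo))
        for ky in range(kh):
            for kx in range(kw):
                xs = xp[:, :, ky:ky + stride * Ho:stride, kx:kx + stride * Wo:stride]
                out += np.einsum("nchw,oc->nohw", xs, w.data[:, :, ky, kx])
        out += b.data[None, :, None, None]

        def bw(g):
            gxp = np.zeros_like(xp)
            gw = np.zeros_like(w.data)
            for ky in range(kh):
                for kx in range(kw):
                    sl = (slice(None), slice(None),
                          slice(ky, ky + stride * Ho, stride),
                          slice(kx, kx + stride * Wo, stride))
                    gw[:, :, ky, kx] = np.einsum("nohw,nchw->oc", g, xp[sl])
                    gxp[sl] += np.einsum("nohw,oc->nchw", g, w.data[:, :, ky, kx])
            x._accumulate(gxp[:, :, padding:padding + H, padding:padding + W])
            w._accumulate(gw)
            b._accumulate(g.sum(axis=(0, 2, 3)))

        return self._make(out, (x, w, b), bw)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor", stride: int = 2,
                         padding: int = 1, output_padding: int = 1):
        """x:(N,C,H,W), weight:(C,O,kh,kw). Adjoint of conv2d; out (N,O,Ho,Wo)."""
        x, w, b = self, weight, bias
        N, C, H, W = x.data.shape
        _, O, kh, kw = w.data.shape
        Ho = (H - 1) * stride - 2 * padding + kh + output_padding
        Wo = (W - 1) * stride - 2 * padding + kw + output_padding
        buf = np.zeros((N, O, Ho + 2 * padding, Wo + 2 * padding))
        for ky in range(kh):
            for kx in range(kw):
                buf[:, :, ky:ky + stride * H:stride, kx:kx + stride * W:stride] += \
                    np.einsum("nchw,co->nohw", x.data, w.data[:, :, ky, kx])
        out = buf[:, :, padding:padding + Ho, padding:padding + Wo] \
            + b.data[None, :, None, None]

        def bw(g):
            gbuf = np.zeros_like(buf)
            gbuf[:, :, padding:padding + Ho, padding:padding + Wo] = g
            gx = np.zeros_like(x.data)
            gw = np.zeros_like(w.data)
            for ky in range(kh):
                for kx in range(kw):
                    gs = gbuf[:, :, ky:ky + stride * H:stride, kx:kx + stride * W:stride]
                    gx += np.einsum("nohw,co->nchw", gs, w.data[:, :, ky, kx])
                    gw[:, :, ky, kx] = np.einsum("nchw,nohw->co", x.data, gs)
            x._accumulate(gx)
            w._accumulate(gw)
            b._accumulate(g.sum(axis=(0, 2, 3)))

        return self._make(out, (x, w, b), bw)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in tensors),
                 _prev=tensors)
    if out.requires_grad:
        out._backward = bw
    return out
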