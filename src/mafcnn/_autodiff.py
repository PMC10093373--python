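"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the package's numeric core for the convolutional feature extractor
and the supervised fine-tuning of the deep belief network.  It supports
exactly the operations those models need: broadcast arithmetic, matmul,
(grouped, strided) 2-D convolution, neighbourhood unfolding for attention,
elementwise nonlinearities, reductions, reshape and concatenation.

Gradients are accumulated by topological traversal of the recorded graph;
every primitive is validated against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ---------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(
                        _unbroadcast(-g * self.data / other.data**2, other.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(g @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ g)
            out._backward = bw
        return out

    def pow(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(
                g * exponent * self.data**(exponent - 1.0))
        return out

    def sqrt(self):
        return self.pow(0.5)

    # ---- nonlinearities ----------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        if out.requires_grad:
            mask = self.data > 0.0
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def clamp_min(self, lo: float):
        out = Tensor(np.maximum(self.data, lo), parents=(self,))
        if out.requires_grad:
            mask = self.data > lo
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    # ---- shape ops ----------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            shape = self.shape

            def bw(g):
                if axis is not None and not keepdims:
                    axes = (axis,) if np.isscalar(axis) else tuple(axis)
                    g = np.expand_dims(g, tuple(a % len(shape) for a in axes))
                self._accumulate(np.broadcast_to(g, shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in ((axis,) if np.isscalar(axis) else axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---- structured ops ----------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, groups: int = 1):
        """2-D cross-correlation, NCHW layout, square kernel."""
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        O, Cg, k, k2 = w.shape
        if k != k2 or C != Cg * groups or O % groups:
            raise ValueError("inconsistent convolution shapes")
        xp = np.pad(x, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
        Ho = (H + 2 * padding - k) // stride + 1
        Wo = (W + 2 * padding - k) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]          # N,C,Ho,Wo,k,k
        cols = (win.reshape(N, groups, Cg, Ho, Wo, k, k)
                   .transpose(0, 1, 3, 4, 2, 5, 6)
                   .reshape(N, groups, Ho, Wo, Cg * k * k))
        wg = w.reshape(groups, O // groups, Cg * k * k)
        out_d = np.einsum("nghwf,gof->ngohw", cols, wg, optimize=True)
        out_d = out_d.reshape(N, O, Ho, Wo)
        if bias is not None:
            out_d = out_d + bias.data.reshape(1, O, 1, 1)
        parents = (self, weight) + ((bias,) if bias is not None else ())
        out = Tensor(out_d, parents=parents)
        if out.requires_grad:
            def bw(g):
                gog = g.reshape(N, groups, O // groups, Ho, Wo)
                if weight.requires_grad:
                    gw = np.einsum("ngohw,nghwf->gof", gog, cols, optimize=True)
                    weight._accumulate(gw.reshape(O, Cg, k, k))
                if bias is not None and bias.requires_grad:
                    bias._accumulate(g.sum(axis=(0, 2, 3)))
                if self.requires_grad:
                    gcols = np.einsum("ngohw,gof->nghwf", gog, wg, optimize=True)
                    gcols = (gcols.reshape(N, groups, Ho, Wo, Cg, k, k)
                                  .transpose(0, 1, 4, 2, 3, 5, 6)
                                  .reshape(N, C, Ho, Wo, k, k))
                    gxp = np.zeros_like(xp)
                    for i in range(k):
                        for j in range(k):
                            gxp[:, :, i:i + stride * Ho:stride,
                                j:j + stride * Wo:stride] += gcols[:, :, :, :, i, j]
                    if padding:
                        gxp = gxp[:, :, padding:-padding, padding:-padding]
                    self._accumulate(gxp)
            out._backward = bw
        return out

    def unfold(self, kernel: int):
        """Extract k×k neighbourhoods (stride 1, same padding).

        Returns shape (N, C, k*k, H, W)."""
        x = self.data
        N, C, H, W = x.shape
        pad = kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad,) * 2, (pad,) * 2))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel),
                                                       axis=(2, 3))
        out_d = win.transpose(0, 1, 4, 5, 2, 3).reshape(N, C, kernel * kernel, H, W)
        out = Tensor(out_d, parents=(self,))
        if out.requires_grad:
            def bw(g):
                gk = g.reshape(N, C, kernel, kernel, H, W)
                gxp = np.zeros_like(xp)
                for i in range(kernel):
                    for j in range(kernel):
                        gxp[:, :, i:i + H, j:j + W] += gk[:, :, i, j]
                if pad:
                    gxp = gxp[:, :, pad:-pad, pad:-pad]
                self._accumulate(gxp)
            out._backward = bw
        return out

    def avg_pool2(self):
        """2×2 average pooling (even spatial dims required)."""
        N, C, H, W = self.shape
        if H % 2 or W % 2:
            raise ValueError("avg_pool2 requires even spatial dimensions")
        r = self.reshape(N, C, H // 2, 2, W // 2, 2)
        return r.mean(axis=(3, 5))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(idx)])
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Shift-stable softmax along `axis` (the shift is a detached constant,
    which is exact because softmax is shift-invariant)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)
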