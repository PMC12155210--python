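"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the multi-task cylinder network needs:
broadcast arithmetic, matmul, reductions, pointwise nonlinearities, 3D
convolution (via sliding windows), average pooling / nearest upsampling,
layer norm, dropout and basic slicing.  Gradients are accumulated through a
topologically sorted backward pass; correctness is covered by
finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv3d", "avg_pool3d", "upsample3d", "layer_norm", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # -- construction helpers -------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in prev), _prev=prev)
        if out.requires_grad:
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g.astype(np.float32)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def pow(self, e: float):
        def backward(g):
            self._accum(g * e * self.data ** (e - 1))

        return self._make(self.data**e, (self,), backward)

    def sqrt(self, eps: float = 0.0):
        out_data = np.sqrt(self.data + eps)

        def backward(g):
            self._accum(g / (2.0 * np.maximum(out_data, 1e-12)))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            gg = np.zeros_like(self.data)
            np.add.at(gg, key, g)
            self._accum(gg)

        return self._make(self.data[key], (self,), backward)

    # -- nonlinearities ---------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0

        def backward(g):
            self._accum(g * np.where(mask, 1.0, slope))

        return self._make(np.where(mask, self.data, slope * self.data), (self,), backward)

    # -- backward driver -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# ---------------------------------------------------------------------------
# structured ops


def conv3d(x: Tensor, w: Tensor, b: Tensor, pad: int = 1) -> Tensor:
    """3D convolution, stride 1.  x: (N, C, D, H, W); w: (O, C, k, k, k)."""
    k = w.shape[2]
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))  # N,C,D,H,W,k,k,k
    out_data = np.einsum("ncdhwijk,ocijk->nodhw", win, w.data, optimize=True) + b.data.reshape(
        1, -1, 1, 1, 1
    )

    def backward(g):
        w._accum(np.einsum("ncdhwijk,nodhw->ocijk", win, g, optimize=True))
        b._accum(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            D, H, W = g.shape[2:]
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        gc = np.einsum("nodhw,oc->ncdhw", g, w.data[:, :, i, j, l], optimize=True)
                        gxp[:, :, i : i + D, j : j + H, l : l + W] += gc
            if pad:
                gxp = gxp[:, :, pad:-pad, pad:-pad, pad:-pad]
            x._accum(gxp)

    out = Tensor(out_data, requires_grad=x.requires_grad or w.requires_grad, _prev=(x, w, b))
    if out.requires_grad:
        out._backward = backward
    return out


def avg_pool3d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping mean pooling by `factor` along the 3 spatial axes."""
    n, c, d, h, w = x.shape
    f = factor
    view = x.data.reshape(n, c, d // f, f, h // f, f, w // f, f)
    out_data = view.mean(axis=(3, 5, 7))

    def backward(g):
        gg = np.repeat(np.repeat(np.repeat(g, f, axis=2), f, axis=3), f, axis=4) / float(f**3)
        x._accum(gg)

    out = Tensor(out_data, requires_grad=x.requires_grad, _prev=(x,))
    if out.requires_grad:
        out._backward = backward
    return out


def upsample3d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling along the 3 spatial axes."""
    f = factor
    out_data = np.repeat(np.repeat(np.repeat(x.data, f, axis=2), f, axis=3), f, axis=4)

    def backward(g):
        n, c, d, h, w = x.shape
        x._accum(g.reshape(n, c, d, f, h, f, w, f).sum(axis=(3, 5, 7)))

    out = Tensor(out_data, requires_grad=x.requires_grad, _prev=(x,))
    if out.requires_grad:
        out._backward = backward
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        beta._accum(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            n = x.shape[-1]
            gx = g * gamma.data
            dx = (
                gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            ) * inv
            x._accum(dx)

    out = Tensor(
        out_data, requires_grad=x.requires_grad or gamma.requires_grad, _prev=(x, gamma, beta)
    )
    if out.requires_grad:
        out._backward = backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity at inference or p == 0."""
    if not training or p <= 0:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)

    def backward(g):
        x._accum(g * mask)

    out = Tensor(x.data * mask, requires_grad=x.requires_grad, _prev=(x,))
    if out.requires_grad:
        out._backward = backward
    return out
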