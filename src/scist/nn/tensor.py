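"""Minimal reverse-mode autodiff on numpy arrays.

A :class:`Tensor` wraps a float64 ``ndarray`` and records the operations
applied to it; :meth:`Tensor.backward` walks the recorded graph in reverse
topological order and accumulates gradients.  The op set is exactly what the
network needs — broadcasting arithmetic, (batched) matmul, reductions, shape
ops, softmax, GELU/ReLU, 2-D convolution and max-pooling — all vectorised, so
small models train at usable speed on a single CPU.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf as _erf

__all__ = ["Tensor", "concat", "index_select"]

_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast axes."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        # first contribution aliases g; later ones allocate (never in-place)
        self.grad = g if self.grad is None else self.grad + g

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic --------------------------------------------------------
    def _sadd(self, s: float):
        out = Tensor(self.data + s, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
        out._backward = bwd
        return out

    def _smul(self, s: float):
        out = Tensor(self.data * s, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s)
        out._backward = bwd
        return out

    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar path keeps the dtype
            return self._sadd(float(other))
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return self._smul(float(other))
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self)._sadd(float(other))
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self._smul(1.0 / other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            return self.__pow__(-1.0)._smul(float(other))
        return self._wrap(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2) if other.data.ndim > 1 \
                    else np.multiply.outer(g, other.data)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g if self.data.ndim > 1 \
                    else np.multiply.outer(self.data, g)
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = bwd
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bwd
        return out

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        cdf = 0.5 * (1.0 + _erf(x * _INV_SQRT2))
        out = Tensor(x * cdf, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
                self._accum(g * (cdf + x * pdf))
        out._backward = bwd
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot))
        out._backward = bwd
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape).copy())
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(gg, self.data.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bwd
        return out

    def normalize(self, gamma: "Tensor", beta: "Tensor", axes: tuple,
                  eps: float = 1e-5, stats_out: dict | None = None) -> "Tensor":
        """Fused (batch/layer) normalisation over ``axes`` with affine params.

        ``gamma``/``beta`` must already be broadcastable against the input.
        ``stats_out``, if given, receives the batch ``mean`` and ``var``
        arrays (for running-statistics bookkeeping).
        """
        x = self.data
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = np.mean(xc * xc, axis=axes, keepdims=True)
        if stats_out is not None:
            stats_out["mean"] = mu
            stats_out["var"] = var
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        out = Tensor(y * gamma.data + beta.data,
                     self.requires_grad or gamma.requires_grad or
                     beta.requires_grad, (self, gamma, beta))

        def bwd(g):
            if gamma.requires_grad:
                gamma._accum(_unbroadcast(g * y, gamma.data.shape))
            if beta.requires_grad:
                beta._accum(_unbroadcast(g, beta.data.shape))
            if self.requires_grad:
                gy = g * gamma.data
                m1 = gy.mean(axis=axes, keepdims=True)
                m2 = (gy * y).mean(axis=axes, keepdims=True)
                self._accum(inv * (gy - m1 - y * m2))
        out._backward = bwd
        return out

    # -- structured ops ----------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 1,
               padding: int = 0) -> "Tensor":
        """2-D cross-correlation, NCHW layout, via im2col."""
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        O, _, kh, kw = w.shape
        s = stride
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        Ho = (xp.shape[2] - kh) // s + 1
        Wo = (xp.shape[3] - kw) // s + 1
        view = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * kh * kw)
        wmat = w.reshape(O, C * kh * kw)
        y = cols @ wmat.T + bias.data
        y = y.transpose(0, 2, 1).reshape(B, O, Ho, Wo)
        out = Tensor(y, self.requires_grad or weight.requires_grad or
                     bias.requires_grad, (self, weight, bias))

        def bwd(g):
            gm = g.reshape(B, O, Ho * Wo).transpose(0, 2, 1)  # B,HoWo,O
            if weight.requires_grad:
                gw = gm.reshape(-1, O).T @ cols.reshape(-1, C * kh * kw)
                weight._accum(gw.reshape(w.shape))
            if bias.requires_grad:
                bias._accum(gm.sum(axis=(0, 1)))
            if self.requires_grad:
                gcols = gm @ wmat  # B,HoWo,C*kh*kw
                gview = gcols.reshape(B, Ho, Wo, C, kh, kw)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                            gview[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                self._accum(gxp)
        out._backward = bwd
        return out

    def maxpool2d(self, kernel: int = 3, stride: int = 2,
                  padding: int = 1) -> "Tensor":
        x = self.data
        B, C, H, W = x.shape
        s = stride
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
        Ho = (xp.shape[2] - kernel) // s + 1
        Wo = (xp.shape[3] - kernel) // s + 1
        view = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::s, ::s]
        flat = view.reshape(B, C, Ho, Wo, kernel * kernel)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                ki, kj = np.divmod(arg, kernel)
                bi, ci, hi, wi = np.indices((B, C, Ho, Wo))
                np.add.at(gxp, (bi, ci, hi * s + ki, wi * s + kj), g)
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                self._accum(gxp)
        out._backward = bwd
        return out

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs exceed the recursion limit
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
        self.grad = np.ones_like(self.data) if grad is None \
            else np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = bwd
    return out


def index_select(t: Tensor, indices: np.ndarray, axis: int) -> Tensor:
    """Gather along ``axis`` (used for seeded token permutations)."""
    indices = np.asarray(indices)
    out = Tensor(np.take(t.data, indices, axis=axis), t.requires_grad, (t,))

    def bwd(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            sl = [slice(None)] * t.data.ndim
            sl[axis] = indices
            np.add.at(full, tuple(sl), g)
            t._accum(full)
    out._backward = bwd
    return out
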