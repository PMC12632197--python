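"""Neural-network building blocks on top of :mod:`scist.nn.tensor`.

Every module takes a ``numpy.random.Generator`` at construction so that all
weight initialisation flows from a single model seed.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, index_select

__all__ = [
    "Module", "Linear", "Conv2d", "BatchNorm2d", "LayerNorm", "Mlp",
    "MultiheadAttention",
]


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self, mode: bool = True) -> "Module":
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        if hasattr(self, "training"):
            self.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def cast(self, dtype) -> "Module":
        """Cast every parameter and float buffer (e.g. to float32)."""
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                v.data = v.data.astype(dtype)
            elif isinstance(v, np.ndarray) and v.dtype.kind == "f":
                self.__dict__[k] = v.astype(dtype)
            elif isinstance(v, Module):
                v.cast(dtype)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.cast(dtype)
        return self

    @property
    def dtype(self):
        return self.parameters()[0].data.dtype

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name -> array map of parameters and buffers (for checkpoints)."""
        out: dict[str, np.ndarray] = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                out[prefix + k] = v.data
            elif isinstance(v, np.ndarray):
                out[prefix + k] = v
            elif isinstance(v, Module):
                out.update(v.state_arrays(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{prefix}{k}.{i}."))
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray],
                          prefix: str = "") -> None:
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                v.data = np.asarray(state[prefix + k])
            elif isinstance(v, np.ndarray):
                self.__dict__[k] = np.asarray(state[prefix + k])
            elif isinstance(v, Module):
                v.load_state_arrays(state, prefix + k + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, f"{prefix}{k}.{i}.")


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = math.sqrt(6.0 / (d_in + d_out))
        self.weight = Tensor(rng.uniform(-bound, bound, (d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        fan_in = c_in * kernel * kernel
        std = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (c_out, c_in, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        if self.training:
            stats: dict = {}
            out = x.normalize(g, b, axes=(0, 2, 3), eps=self.eps,
                              stats_out=stats)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * stats["mean"].ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * stats["var"].ravel())
            return out
        inv = 1.0 / np.sqrt(self.running_var.reshape(1, -1, 1, 1) + self.eps)
        scale = inv  # constant w.r.t. the graph in eval mode
        return (x - self.running_mean.reshape(1, -1, 1, 1)) * scale * g + b


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.normalize(self.gamma, self.beta, axes=(-1,), eps=self.eps)


class Mlp(Module):
    """Linear -> GELU -> Linear."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int,
                 rng: np.random.Generator):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class MultiheadAttention(Module):
    """Scaled-dot-product attention with separate q/k/v/out projections.

    ``__call__`` accepts an optional seeded token permutation for the key and
    value streams (the scramble ablation) and an optional ``record`` dict
    which receives the softmax attention weights (instrumentation).
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        return x.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, q: Tensor, k: Tensor, v: Tensor,
                 kv_perm: np.ndarray | None = None,
                 record: dict | None = None) -> Tensor:
        if kv_perm is not None:
            k = index_select(k, kv_perm, axis=1)
            v = index_select(v, kv_perm, axis=1)
        B, Tq, D = q.shape
        qh = self._split(self.wq(q))
        kh = self._split(self.wk(k))
        vh = self._split(self.wv(v))
        scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        if record is not None:
            record.setdefault("attention_weights", []).append(attn.data.copy())
        out = attn @ vh
        out = out.transpose(0, 2, 1, 3).reshape(B, Tq, D)
        return self.wo(out)
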