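"""Minimal neural-network layers on NumPy arrays with explicit backprop.

Every module operates on a single example shaped ``(positions, channels)``
(batch size 1, which is also the training protocol) and implements a
``forward``/``backward`` pair. ``backward`` consumes the gradient of the
loss with respect to the module output and returns the gradient with
respect to its input, accumulating parameter gradients in place. All
backward passes are verified against central finite differences in the
test suite.

Weight initialization mirrors the Kaiming-uniform default of mainstream
deep-learning frameworks: weights and biases drawn from
U(-1/sqrt(fan_in), 1/sqrt(fan_in)), reproducible from a seeded Generator.
"""

from __future__ import annotations

import math
from typing import Iterator, List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ShapeError

DTYPE = np.float64


class Param:
    """A named, trainable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad", "trainable", "group")

    def __init__(self, name: str, value: np.ndarray, group: str = "trunk",
                 trainable: bool = True):
        self.name = name
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.group = group

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Module:
    """Base class; subclasses cache whatever forward state backward needs."""

    group = "trunk"

    def parameters(self) -> Iterator[Param]:
        for v in vars(self).values():
            if isinstance(v, Param):
                yield v
            elif isinstance(v, Module):
                yield from v.parameters()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def forward(self, x, *, train: bool = False,
                rng: Optional[np.random.Generator] = None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Linear(Module):
    def __init__(self, name: str, c_in: int, c_out: int,
                 rng: np.random.Generator, group: str = "trunk",
                 bias: bool = True):
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(f"{name}.weight", _uniform(rng, (c_in, c_out), c_in), group)
        self.b = Param(f"{name}.bias", _uniform(rng, (c_out,), c_in), group) if bias else None

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        if self.b is not None:
            self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Conv1d(Module):
    """Same-padded 1-D convolution (cross-correlation), stride 1."""

    def __init__(self, name: str, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, group: str = "trunk"):
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel
        self.W = Param(f"{name}.weight", _uniform(rng, (kernel * c_in, c_out), fan_in), group)
        self.b = Param(f"{name}.bias", _uniform(rng, (c_out,), fan_in), group)
        self.pad_l = (kernel - 1) // 2
        self.pad_r = kernel - 1 - self.pad_l

    def _patches(self, x):
        xp = np.pad(x, ((self.pad_l, self.pad_r), (0, 0)))
        # (L, C, k) -> (L, k, C) -> (L, k*C); matches W layout (k*C, c_out)
        win = sliding_window_view(xp, self.kernel, axis=0)
        return np.ascontiguousarray(win.transpose(0, 2, 1)).reshape(x.shape[0], -1)

    def forward(self, x, *, train=False, rng=None):
        self._L = x.shape[0]
        self._P = self._patches(x)
        return self._P @ self.W.value + self.b.value

    def backward(self, dy):
        L, k, c = self._L, self.kernel, self.c_in
        self.W.grad += self._P.T @ dy
        self.b.grad += dy.sum(axis=0)
        dP = (dy @ self.W.value.T).reshape(L, k, c)
        dxp = np.zeros((L + k - 1, c), dtype=DTYPE)
        for j in range(k):
            dxp[j:j + L] += dP[:, j, :]
        return dxp[self.pad_l:self.pad_l + L]


class LayerNorm(Module):
    def __init__(self, name: str, c: int, group: str = "trunk", eps: float = 1e-5):
        self.eps = eps
        self.g = Param(f"{name}.gain", np.ones(c), group)
        self.b = Param(f"{name}.bias", np.zeros(c), group)

    def forward(self, x, *, train=False, rng=None):
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.g.value * self._xhat + self.b.value

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        self.g.grad += (dy * xhat).sum(axis=0)
        self.b.grad += dy.sum(axis=0)
        dxhat = dy * self.g.value
        n = xhat.shape[1]
        return inv * (
            dxhat
            - dxhat.mean(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
        )


_GELU_C = math.sqrt(2.0 / math.pi)


class GELU(Module):
    """tanh-approximation GELU."""

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        self._t = np.tanh(_GELU_C * (x + 0.044715 * x ** 3))
        return 0.5 * x * (1.0 + self._t)

    def backward(self, dy):
        x, t = self._x, self._t
        dt = (1.0 - t ** 2) * _GELU_C * (1.0 + 3 * 0.044715 * x ** 2)
        return dy * (0.5 * (1.0 + t) + 0.5 * x * dt)


class Softplus(Module):
    """Numerically stable softplus; guarantees strictly positive output."""

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return np.logaddexp(0.0, x)

    def backward(self, dy):
        return dy / (1.0 + np.exp(-self._x))


class Dropout(Module):
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class AttentionPool(Module):
    """Softmax-weighted pooling by a factor of 2 with a learned per-channel
    temperature (initialized at 2, biasing toward max-like pooling)."""

    def __init__(self, name: str, c: int, group: str = "trunk"):
        self.gain = Param(f"{name}.gain", np.full(c, 2.0), group)

    def forward(self, x, *, train=False, rng=None):
        L, C = x.shape
        if L % 2:
            raise ShapeError(f"AttentionPool needs even length, got {L}")
        r = x.reshape(L // 2, 2, C)
        z = self.gain.value * r
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        a = e / e.sum(axis=1, keepdims=True)
        self._r, self._a = r, a
        return (a * r).sum(axis=1)

    def backward(self, dy):
        r, a, g = self._r, self._a, self.gain.value
        dyb = dy[:, None, :]
        da = dyb * r
        dz = a * (da - (da * a).sum(axis=1, keepdims=True))
        self.gain.grad += (dz * r).sum(axis=(0, 1))
        dr = a * dyb + dz * g
        return dr.reshape(-1, r.shape[2])


class MaxPool(Module):
    """Max pooling by a factor of 2."""

    def forward(self, x, *, train=False, rng=None):
        L, C = x.shape
        if L % 2:
            raise ShapeError(f"MaxPool needs even length, got {L}")
        r = x.reshape(L // 2, 2, C)
        self._idx = r.argmax(axis=1)
        self._shape = r.shape
        return np.take_along_axis(r, self._idx[:, None, :], axis=1)[:, 0, :]

    def backward(self, dy):
        dr = np.zeros(self._shape, dtype=DTYPE)
        np.put_along_axis(dr, self._idx[:, None, :], dy[:, None, :], axis=1)
        return dr.reshape(-1, self._shape[2])


class CenterCrop(Module):
    """Keep the central ``keep`` rows; gradients for cropped rows are zero."""

    def __init__(self, keep: int):
        self.keep = keep

    def forward(self, x, *, train=False, rng=None):
        self._L = x.shape[0]
        self._lo = (self._L - self.keep) // 2
        return x[self._lo:self._lo + self.keep]

    def backward(self, dy):
        dx = np.zeros((self._L, dy.shape[1]), dtype=DTYPE)
        dx[self._lo:self._lo + self.keep] = dy
        return dx


class MultiHeadAttention(Module):
    """Multi-head self-attention over a fixed number of positions.

    Positional information enters as a learned bias added to the attention
    logits: symmetric in distance ``|i-j|`` under the ``relative_bias``
    scheme, direction-aware in the offset ``i-j`` under ``learned_relative``,
    or absent (``none``). The output projection is optional — when removed,
    the concatenated heads (whose total width must then equal the residual
    width) feed the residual stream directly.
    """

    def __init__(self, name: str, c: int, n_heads: int, head_dim: int,
                 n_positions: int, scheme: str, use_out_proj: bool,
                 rng: np.random.Generator, group: str = "trunk"):
        self.H, self.D, self.P = n_heads, head_dim, n_positions
        hd = n_heads * head_dim
        self.Wq = Param(f"{name}.q", _uniform(rng, (c, hd), c), group)
        self.Wk = Param(f"{name}.k", _uniform(rng, (c, hd), c), group)
        self.Wv = Param(f"{name}.v", _uniform(rng, (c, hd), c), group)
        self.scheme = scheme
        if scheme == "relative_bias":
            self.bias = Param(f"{name}.rel_bias", np.zeros((n_heads, n_positions)), group)
            self._dist = np.abs(np.arange(n_positions)[:, None] - np.arange(n_positions)[None, :])
        elif scheme == "learned_relative":
            self.bias = Param(f"{name}.rel_bias", np.zeros((n_heads, 2 * n_positions - 1)), group)
            self._dist = (np.arange(n_positions)[:, None] - np.arange(n_positions)[None, :]) + n_positions - 1
        else:
            self.bias = None
        self.out = Linear(f"{name}.out", hd, c, rng, group) if use_out_proj else None
        self.scale = 1.0 / math.sqrt(head_dim)

    def forward(self, x, *, train=False, rng=None):
        P, H, D = x.shape[0], self.H, self.D
        if P != self.P:
            raise ShapeError(f"attention built for {self.P} positions, got {P}")
        self._x = x
        q = (x @ self.Wq.value).reshape(P, H, D)
        k = (x @ self.Wk.value).reshape(P, H, D)
        v = (x @ self.Wv.value).reshape(P, H, D)
        logits = np.einsum("ihd,jhd->hij", q, k) * self.scale
        if self.bias is not None:
            logits = logits + self.bias.value[:, self._dist]
        logits -= logits.max(axis=2, keepdims=True)
        e = np.exp(logits)
        a = e / e.sum(axis=2, keepdims=True)
        o = np.einsum("hij,jhd->ihd", a, v)
        self._q, self._k, self._v, self._a = q, k, v, a
        y = o.reshape(P, H * D)
        if self.out is not None:
            self._o = y
            y = self.out.forward(y)
        return y

    def backward(self, dy):
        P, H, D = self.P, self.H, self.D
        if self.out is not None:
            dy = self.out.backward(dy)
        do = dy.reshape(P, H, D)
        a, q, k, v, x = self._a, self._q, self._k, self._v, self._x
        dv = np.einsum("hij,ihd->jhd", a, do)
        da = np.einsum("ihd,jhd->hij", do, v)
        dlog = a * (da - (da * a).sum(axis=2, keepdims=True))
        if self.bias is not None:
            flat = self._dist.ravel()
            n = self.bias.value.shape[1]
            for h in range(H):
                self.bias.grad[h] += np.bincount(flat, weights=dlog[h].ravel(), minlength=n)
        dq = np.einsum("hij,jhd->ihd", dlog, k) * self.scale
        dk = np.einsum("hij,ihd->jhd", dlog, q) * self.scale
        dx = dq.reshape(P, H * D) @ self.Wq.value.T
        dx += dk.reshape(P, H * D) @ self.Wk.value.T
        dx += dv.reshape(P, H * D) @ self.Wv.value.T
        self.Wq.grad += x.T @ dq.reshape(P, H * D)
        self.Wk.grad += x.T @ dk.reshape(P, H * D)
        self.Wv.grad += x.T @ dv.reshape(P, H * D)
        return dx


class Sequential(Module):
    def __init__(self, modules: List[Module]):
        self.modules = list(modules)

    def forward(self, x, *, train=False, rng=None):
        for m in self.modules:
            x = m.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy


class Residual(Module):
    """y = x + inner(x)."""

    def __init__(self, inner: Module):
        self.inner = inner

    def forward(self, x, *, train=False, rng=None):
        return x + self.inner.forward(x, train=train, rng=rng)

    def backward(self, dy):
        return dy + self.inner.backward(dy)
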