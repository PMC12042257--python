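"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for a small pre-norm encoder-decoder transformer:
broadcast add/mul, batched matmul, reshape/transpose, softmax, RMS
normalization, embedding gather, SiLU/ReLU, and a fused masked
softmax-cross-entropy.  Gradients are accumulated on a tape and released
by :meth:`Tensor.backward`; everything runs in float64 so analytic
gradients can be checked against finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "embedding", "rms_norm", "softmax",
           "cross_entropy", "silu", "relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "_backward", "_prev")

    def __init__(self, data, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._backward = lambda: None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    def _ensure_grad(self):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)

    # ---- graph construction -------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def _backward():
            self._ensure_grad()
            other._ensure_grad()
            self.grad += _unbroadcast(out.grad, self.data.shape)
            other.grad += _unbroadcast(out.grad, other.data.shape)

        out._backward = _backward
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def _backward():
            self._ensure_grad()
            other._ensure_grad()
            self.grad += _unbroadcast(out.grad * other.data, self.data.shape)
            other.grad += _unbroadcast(out.grad * self.data, other.data.shape)

        out._backward = _backward
        return out

    def scale(self, s: float):
        out = Tensor(self.data * s, (self,))

        def _backward():
            self._ensure_grad()
            self.grad += out.grad * s

        out._backward = _backward
        return out

    def add_const(self, arr: np.ndarray):
        """Add a non-differentiable array (e.g. an attention mask)."""
        out = Tensor(self.data + arr, (self,))

        def _backward():
            self._ensure_grad()
            self.grad += _unbroadcast(out.grad, self.data.shape)

        out._backward = _backward
        return out

    def matmul(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(np.matmul(self.data, other.data), (self, other))

        def _backward():
            self._ensure_grad()
            other._ensure_grad()
            bt = np.swapaxes(other.data, -1, -2)
            at = np.swapaxes(self.data, -1, -2)
            self.grad += _unbroadcast(np.matmul(out.grad, bt), self.data.shape)
            other.grad += _unbroadcast(np.matmul(at, out.grad), other.data.shape)

        out._backward = _backward
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def _backward():
            self._ensure_grad()
            self.grad += out.grad.reshape(self.data.shape)

        out._backward = _backward
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), (self,))
        inv = np.argsort(axes)

        def _backward():
            self._ensure_grad()
            self.grad += out.grad.transpose(inv)

        out._backward = _backward
        return out

    # ---- backward -----------------------------------------------------------

    def backward(self):
        topo: list[Tensor] = []
        visited = set()

        def build(t: Tensor):
            if id(t) not in visited:
                visited.add(id(t))
                for p in t._prev:
                    build(p)
                topo.append(t)

        build(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            t._backward()


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))

    def _backward():
        x._ensure_grad()
        x.grad += out.grad * (x.data > 0)

    out._backward = _backward
    return out


def silu(x: Tensor) -> Tensor:
    sig = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(x.data * sig, (x,))

    def _backward():
        x._ensure_grad()
        x.grad += out.grad * (sig * (1.0 + x.data * (1.0 - sig)))

    out._backward = _backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, (x,))

    def _backward():
        x._ensure_grad()
        g = out.grad
        x.grad += s * (g - (g * s).sum(axis=axis, keepdims=True))

    out._backward = _backward
    return out


def rms_norm(x: Tensor, weight: Tensor, eps: float = 1e-6) -> Tensor:
    """T5-style layer norm: no mean subtraction, no bias."""
    ms = (x.data ** 2).mean(axis=-1, keepdims=True)
    r = 1.0 / np.sqrt(ms + eps)
    out = Tensor(x.data * r * weight.data, (x, weight))

    def _backward():
        x._ensure_grad()
        weight._ensure_grad()
        g = out.grad
        d = x.data.shape[-1]
        gw = g * weight.data
        x.grad += gw * r - x.data * (r ** 3) * (gw * x.data).mean(
            axis=-1, keepdims=True
        )
        weight.grad += (g * x.data * r).reshape(-1, d).sum(axis=0)

    out._backward = _backward
    return out


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)
    out = Tensor(table.data[ids], (table,))

    def _backward():
        table._ensure_grad()
        np.add.at(table.grad, ids, out.grad)

    out._backward = _backward
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  mask: np.ndarray | None = None) -> Tensor:
    """Mean masked token-level cross entropy.

    ``logits``: (..., V); ``targets``: integer array matching the leading
    shape; ``mask``: same leading shape, 1 where the token counts.
    """
    targets = np.asarray(targets)
    if mask is None:
        mask = np.ones(targets.shape, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    m = logits.data.max(axis=-1, keepdims=True)
    z = logits.data - m
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    picked = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
    denom = mask.sum()
    if denom == 0:
        raise ValueError("empty loss mask")
    out = Tensor(-(picked * mask).sum() / denom, (logits,))

    def _backward():
        logits._ensure_grad()
        p = np.exp(logp)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, targets[..., None], 1.0, axis=-1)
        logits.grad += out.grad * mask[..., None] * (p - onehot) / denom

    out._backward = _backward
    return out


class Adam:
    """Plain Adam over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
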