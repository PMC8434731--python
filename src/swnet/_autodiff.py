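"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the response model needs: broadcast-aware
arithmetic, matmul, relu/sigmoid, reductions, gather/segment-sum (for message
passing on graphs), 1D convolution/pooling and batch normalization.  Gradients
accumulate into ``Tensor.grad`` after calling :meth:`Tensor.backward` on a
scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "relu", "sigmoid", "conv1d", "maxpool1d", "batchnorm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = _parents

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        needs = any(p.requires_grad or p._parents for p in parents)
        out = Tensor(data, _parents=tuple(parents) if needs else ())
        if needs:
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return self._make(self.data / other.data, (self, other), bw)

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 2 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(a.T @ g)
            elif a.ndim == 1 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(np.outer(a, g))
            elif a.ndim == 2 and b.ndim == 1:
                self._accum(np.outer(g, b))
                other._accum(a.T @ g)
            else:  # batched (B, m, k) @ (B, k, n)
                self._accum(g @ np.swapaxes(b, -1, -2))
                other._accum(np.swapaxes(a, -1, -2) @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # -- shaping -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bw)

    @property
    def T(self):
        def bw(g):
            self._accum(g.T)

        return self._make(self.data.T, (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, idx, g)

        return self._make(self.data[idx], (self,), bw)

    def gather_rows(self, idx) -> "Tensor":
        """Row gather with duplicate-safe gradient scatter-add."""
        idx = np.asarray(idx)
        return self[idx]

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def segment_sum(self, segment_ids, num_segments: int) -> "Tensor":
        """Sum rows sharing a segment id; rows of the output are segments."""
        segment_ids = np.asarray(segment_ids)
        out = np.zeros((num_segments,) + self.data.shape[1:])
        np.add.at(out, segment_ids, self.data)

        def bw(g):
            self._accum(g[segment_ids])

        return self._make(out, (self,), bw)


# -- nonlinearities ---------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accum(g * mask)

    return x._make(x.data * mask, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x._accum(g * s * (1.0 - s))

    return x._make(s, (x,), bw)


def concat(tensors, axis=0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    needs = any(t.requires_grad or t._parents for t in tensors)
    if needs:
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]

    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    if any(t.requires_grad or t._parents for t in tensors):
        out._parents = tuple(tensors)
        out._backward = bw
    return out


# -- neural-network primitives ----------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, C, L) -> (B, C*k, L_out) column view (copied)."""
    B, C, L = x.shape
    L_out = (L - k) // stride + 1
    cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::stride, :]
    # cols: (B, C, L_out, k) -> (B, C*k, L_out)
    return cols.transpose(0, 1, 3, 2).reshape(B, C * k, L_out)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1) -> Tensor:
    """1D convolution: x (B, C_in, L), weight (C_out, C_in, K), bias (C_out,)."""
    B, C_in, L = x.data.shape
    C_out, _, K = weight.data.shape
    L_out = (L - K) // stride + 1
    if L_out < 1:
        raise ValueError(f"conv1d: input length {L} shorter than kernel {K}")
    cols = _im2col(x.data, K, stride)  # (B, C_in*K, L_out)
    W2 = weight.data.reshape(C_out, C_in * K)
    out = np.einsum("ok,bkl->bol", W2, cols) + bias.data[None, :, None]

    def bw(g):
        # g: (B, C_out, L_out)
        bias._accum(g.sum(axis=(0, 2)))
        dW2 = np.einsum("bol,bkl->ok", g, cols)
        weight._accum(dW2.reshape(C_out, C_in, K))
        dcols = np.einsum("ok,bol->bkl", W2, g)  # (B, C_in*K, L_out)
        dx = np.zeros_like(x.data)
        dcols = dcols.reshape(B, C_in, K, L_out)
        for j in range(K):
            np.add.at(dx, (slice(None), slice(None), slice(j, j + stride * L_out, stride)), dcols[:, :, j, :])
        x._accum(dx)

    return x._make(out, (x, weight, bias), bw)


def maxpool1d(x: Tensor, width: int = 2) -> Tensor:
    """Non-overlapping max pooling over the last axis (trailing remainder dropped)."""
    B, C, L = x.data.shape
    L_out = L // width
    xv = x.data[:, :, : L_out * width].reshape(B, C, L_out, width)
    arg = xv.argmax(axis=3)
    out = np.take_along_axis(xv, arg[..., None], axis=3)[..., 0]

    def bw(g):
        dx = np.zeros_like(x.data)
        dxv = dx[:, :, : L_out * width].reshape(B, C, L_out, width)
        np.put_along_axis(dxv, arg[..., None], g[..., None], axis=3)
        x._accum(dx)

    return x._make(out, (x,), bw)


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization on (B, C, L); updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2))
        var = x.data.var(axis=(0, 2))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None]) * inv[None, :, None]
    out = gamma.data[None, :, None] * xhat + beta.data[None, :, None]

    def bw(g):
        beta._accum(g.sum(axis=(0, 2)))
        gamma._accum((g * xhat).sum(axis=(0, 2)))
        gx = g * gamma.data[None, :, None]
        if training:
            n = x.data.shape[0] * x.data.shape[2]
            s1 = gx.sum(axis=(0, 2))
            s2 = (gx * xhat).sum(axis=(0, 2))
            dx = inv[None, :, None] * (gx - (s1[None, :, None] + xhat * s2[None, :, None]) / n)
        else:
            dx = gx * inv[None, :, None]
        x._accum(dx)

    return x._make(out, (x, gamma, beta), bw)
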