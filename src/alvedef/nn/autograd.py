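"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the primitives the shifted-window
transformer and its decoder need: broadcast-aware arithmetic, batched matmul,
shape manipulation (reshape/transpose/pad/slice/roll/concat), fused softmax,
layer norm, GELU, gather, and the two supervision losses (binary cross
entropy with logits, mean squared error).  Everything is float32 and runs on
the CPU; gradients are accumulated by topological traversal of the tape.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "Parameter", "no_grad"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw", "_grad_owned")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _bw: Callable[[np.ndarray], None] | None = None,
    ):
        if isinstance(data, np.ndarray) and data.dtype == np.float32:
            self.data = data
        else:
            self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self._grad_owned = False
        self.requires_grad = (
            requires_grad or any(p.requires_grad for p in _parents)
        ) and _GRAD_ENABLED[0]
        self._parents = _parents if self.requires_grad else ()
        self._bw = _bw if self.requires_grad else None

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        # copy-on-write: borrow the incoming buffer on first accumulation,
        # materialise an owned copy only if a second gradient arrives
        if self.grad is None:
            self.grad = g if g.dtype == np.float32 else g.astype(np.float32)
            self._grad_owned = False
        elif not self._grad_owned:
            self.grad = self.grad + g
            self._grad_owned = True
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _bw=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _bw=bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _bw=bw)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data
        out_data = a @ b

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, b.shape))

        return Tensor(out_data, _parents=(self, other), _bw=bw)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(shape), _parents=(self,), _bw=bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inverse))

        return Tensor(self.data.transpose(axes), _parents=(self,), _bw=bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full)

        return Tensor(self.data[idx], _parents=(self,), _bw=bw)

    def pad2d(self, pad_h: tuple[int, int], pad_w: tuple[int, int], axes: tuple[int, int]):
        """Zero-pad two axes (typically the spatial H, W axes)."""
        widths = [(0, 0)] * self.data.ndim
        widths[axes[0]] = pad_h
        widths[axes[1]] = pad_w
        sl = [slice(None)] * self.data.ndim
        sl[axes[0]] = slice(pad_h[0], pad_h[0] + self.data.shape[axes[0]])
        sl[axes[1]] = slice(pad_w[0], pad_w[0] + self.data.shape[axes[1]])
        sl = tuple(sl)

        def bw(g):
            self._accumulate(g[sl])

        return Tensor(np.pad(self.data, widths), _parents=(self,), _bw=bw)

    def roll(self, shifts: tuple[int, int], axes: tuple[int, int]):
        def bw(g):
            self._accumulate(np.roll(g, (-shifts[0], -shifts[1]), axis=axes))

        return Tensor(np.roll(self.data, shifts, axis=axes), _parents=(self,), _bw=bw)

    def take(self, index: np.ndarray):
        """Gather rows of a 2-D table by an integer index array."""
        index = np.asarray(index)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, index.ravel(), g.reshape(-1, g.shape[-1]))
            self._accumulate(full)

        return Tensor(self.data[index], _parents=(self,), _bw=bw)

    # -- reductions & activations -------------------------------------------
    def sum(self):
        def bw(g):
            self._accumulate(np.broadcast_to(g, self.data.shape).astype(np.float32))

        return Tensor(self.data.sum(), _parents=(self,), _bw=bw)

    def mean(self):
        n = self.data.size

        def bw(g):
            self._accumulate(np.broadcast_to(g / n, self.data.shape).astype(np.float32))

        return Tensor(self.data.mean(), _parents=(self,), _bw=bw)

    def relu(self):
        pos = self.data > 0

        def bw(g):
            self._accumulate(g * pos)

        return Tensor(self.data * pos, _parents=(self,), _bw=bw)

    def gelu(self):
        """Exact (erf-based) GELU, computed in float32."""
        from scipy.special import erf

        x = self.data
        phi = erf(x * np.float32(1.0 / math.sqrt(2.0)))
        phi += np.float32(1.0)
        phi *= np.float32(0.5)
        out = x * phi
        dphi = np.exp(np.float32(-0.5) * x * x) * np.float32(1.0 / math.sqrt(2.0 * math.pi))
        local = phi + x * dphi

        def bw(g):
            self._accumulate(g * local)

        return Tensor(out, _parents=(self,), _bw=bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor(s.astype(np.float32), _parents=(self,), _bw=bw)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        return Tensor(s.astype(np.float32), _parents=(self,), _bw=bw)

    def layer_norm(self, weight: "Tensor", bias: "Tensor", eps: float = 1e-5):
        """Normalise the last axis, then apply an affine (gamma, beta)."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = xhat * weight.data + bias.data
        n = x.shape[-1]

        def bw(g):
            if weight.requires_grad:
                weight._accumulate((g * xhat).reshape(-1, n).sum(axis=0))
            if bias.requires_grad:
                bias._accumulate(g.reshape(-1, n).sum(axis=0))
            if self.requires_grad:
                gx = g * weight.data
                term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(
                    axis=-1, keepdims=True
                )
                self._accumulate(term * inv)

        return Tensor(out.astype(np.float32), _parents=(self, weight, bias), _bw=bw)

    # -- losses --------------------------------------------------------------
    def bce_with_logits(self, target: np.ndarray, pos_weight: float = 1.0) -> "Tensor":
        """Mean binary cross entropy on logits (numerically stable).

        ``pos_weight`` scales the positive-target term, the standard remedy
        for heavy foreground/background imbalance.
        """
        x = self.data
        t = np.asarray(target, dtype=np.float32)
        zero = np.float32(0.0)
        log_sig = -np.logaddexp(zero, -x)  # log sigmoid(x)
        log_one_minus = -np.logaddexp(zero, x)
        loss = -(pos_weight * t * log_sig + (1.0 - t) * log_one_minus)
        n = x.size
        s = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

        def bw(g):
            grad = (s * (1.0 + (pos_weight - 1.0) * t) - pos_weight * t) / n
            self._accumulate(g * grad.astype(np.float32))

        return Tensor(np.float32(loss.mean()), _parents=(self,), _bw=bw)

    def mse(self, target: np.ndarray) -> "Tensor":
        t = np.asarray(target, dtype=np.float32)
        diff = self.data - t
        n = diff.size

        def bw(g):
            self._accumulate(g * (2.0 / n) * diff)

        return Tensor(np.float32(np.mean(diff * diff)), _parents=(self,), _bw=bw)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors), _bw=bw)


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)
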