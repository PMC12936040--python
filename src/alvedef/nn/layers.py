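"""Neural-network building blocks on top of the autograd engine.

Feature maps are kept channel-last ``(B, H, W, C)`` throughout so that
linear layers, layer norm and attention all operate on the trailing axis.
Convolutions are realised with im2col and one large matrix product; the
stride-2 transposed convolution used for decoder upsampling is expressed as
a linear map followed by depth-to-space, which is algebraically identical to
a kernel-2/stride-2 transposed convolution.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "Mlp",
    "Conv2d",
    "Upsample2x",
    "AdamW",
    "cosine_lr",
]


class Module:
    """Parameter container with recursive traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return params

    def named_parameters(self) -> list[tuple[str, Tensor]]:
        named: list[tuple[str, Tensor]] = []
        seen: set[int] = set()

        def walk(obj, prefix):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    named.append((prefix, obj))
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    walk(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}.{i}")
            elif isinstance(obj, dict):
                for k, v in obj.items():
                    walk(v, f"{prefix}.{k}")

        walk(self, "")
        return named

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = dict(self.named_parameters())
        missing = set(named) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in named.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(np.float32).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Parameter(
            rng.normal(0.0, 0.02, size=(in_features, out_features)).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.weight, self.bias, self.eps)


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class Conv2d(Module):
    """`k x k`, stride-1, same-padded convolution on (B, H, W, C) features."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("Conv2d supports odd kernel sizes")
        scale = float(np.sqrt(2.0 / (k * k * c_in)))
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(k * k * c_in, c_out)).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))
        self.k = k
        self.c_in = c_in

    def __call__(self, x: Tensor) -> Tensor:
        k = self.k
        b, h, w, c = x.shape
        pad = k // 2
        xp = x.pad2d((pad, pad), (pad, pad), axes=(1, 2))
        cols = _im2col(xp, k)  # (B, H, W, k*k*C) as Tensor
        out = cols.reshape(b * h * w, k * k * c) @ self.weight + self.bias
        return out.reshape(b, h, w, self.weight.shape[1])


def _im2col(xp: Tensor, k: int) -> Tensor:
    """Gather k x k neighbourhoods of a padded (B, H+2p, W+2p, C) tensor.

    Implemented with a custom fused op: forward uses stride tricks, backward
    scatters the column gradient back with k*k vectorised adds.
    """
    data = xp.data
    b, hp, wp, c = data.shape
    h, w = hp - (k - 1), wp - (k - 1)
    s0, s1, s2, s3 = data.strides
    view = np.lib.stride_tricks.as_strided(
        data, shape=(b, h, w, k, k, c), strides=(s0, s1, s2, s1, s2, s3)
    )
    out = view.reshape(b, h, w, k * k * c).copy()

    def bw(g):
        g6 = g.reshape(b, h, w, k, k, c)
        full = np.zeros_like(data)
        for i in range(k):
            for j in range(k):
                full[:, i : i + h, j : j + w, :] += g6[:, :, :, i, j, :]
        xp._accumulate(full)

    return Tensor(out, _parents=(xp,), _bw=bw)


class Upsample2x(Module):
    """Kernel-2, stride-2 transposed convolution (as linear + depth-to-space)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = float(np.sqrt(2.0 / c_in))
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(c_in, 4 * c_out)).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(4 * c_out, dtype=np.float32))
        self.c_out = c_out

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        y = x @ self.weight + self.bias  # (B, H, W, 4*C_out)
        y = y.reshape(b, h, w, 2, 2, self.c_out)
        y = y.transpose(0, 1, 3, 2, 4, 5)  # (B, H, 2, W, 2, C_out)
        return y.reshape(b, 2 * h, 2 * w, self.c_out)


class AdamW:
    """AdamW with decoupled weight decay (applied to >=2-D weights only)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.data.ndim >= 2:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(epoch: int, total_epochs: int, lr0: float, lr_min: float = 0.0) -> float:
    """Cosine annealing from ``lr0`` down to ``lr_min`` over ``total_epochs``."""
    if total_epochs <= 1:
        return lr0
    t = epoch / (total_epochs - 1)
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + np.cos(np.pi * t))
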