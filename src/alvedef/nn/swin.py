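"""2D Swin-UNETR: hierarchical shifted-window transformer encoder with a
skip-connected convolutional decoder.

The encoder stacks Swin transformer blocks in four stages.  Each block
computes self-attention inside non-overlapping ``window_size`` windows
(with a learned relative position bias); alternating blocks cyclically
shift the windows by half their extent, masking attention across the
wrap-around seam, so information propagates between windows.  Patch merging
between stages halves the spatial resolution and doubles the channel width.
The decoder recovers full resolution with stride-2 transposed convolutions,
concatenating the matching encoder feature map at every level, and ends in
a 12-channel head (4 defect-class groups x [mask/heatmap, d_x, d_y]).

Feature maps that are not divisible by the window or merging factor are
zero-padded and the result cropped back, deterministically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autograd import Tensor, concat
from .layers import Conv2d, LayerNorm, Linear, Mlp, Module, Upsample2x

__all__ = [
    "NetConfig",
    "WindowAttention",
    "SwinBlock",
    "PatchMerging",
    "SwinUNETR2D",
    "window_partition",
    "window_reverse",
    "apply_window_attention",
]


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters of the 2D Swin-UNETR."""

    patch_size: int = 2
    embed_dim: int = 24
    depths: tuple[int, int, int, int] = (2, 2, 2, 2)
    num_heads: tuple[int, int, int, int] = (3, 6, 12, 24)
    window_size: int = 7
    mlp_ratio: float = 4.0
    out_channels: int = 12
    in_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.depths) != 4 or len(self.num_heads) != 4:
            raise ValueError("the encoder has exactly 4 stages")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.out_channels != 12:
            raise ValueError("the prediction head has exactly 12 channels")
        for s, h in enumerate(self.num_heads):
            if (self.embed_dim * 2**s) % h:
                raise ValueError(f"stage {s} width not divisible by {h} heads")

    @classmethod
    def tiny(cls, seed: int = 0) -> "NetConfig":
        """Small preset (< 1M parameters) for CPU training and tests."""
        return cls(embed_dim=12, window_size=4, seed=seed)

    @property
    def total_downsampling(self) -> int:
        return self.patch_size * 2 ** (len(self.depths) - 1)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "NetConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        raw["depths"] = tuple(raw["depths"])
        raw["num_heads"] = tuple(raw["num_heads"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# window partitioning

def window_partition(x: Tensor, ws: int) -> Tensor:
    """(B, H, W, C) -> (B * nWindows, ws*ws, C); H, W divisible by ws."""
    b, h, w, c = x.shape
    x = x.reshape(b, h // ws, ws, w // ws, ws, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b * (h // ws) * (w // ws), ws * ws, c)


def window_reverse(x: Tensor, ws: int, b: int, h: int, w: int) -> Tensor:
    c = x.shape[-1]
    x = x.reshape(b, h // ws, w // ws, ws, ws, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, h, w, c)


def _relative_position_index(ws: int) -> np.ndarray:
    coords = np.stack(np.meshgrid(np.arange(ws), np.arange(ws), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]  # (2, T, T)
    rel = rel + (ws - 1)
    return rel[0] * (2 * ws - 1) + rel[1]  # (T, T) in [0, (2ws-1)^2)


def _shift_attention_mask(hp: int, wp: int, ws: int, shift: int) -> np.ndarray:
    """Additive mask (nWindows, T, T) forbidding attention across the
    wrap-around seams introduced by the cyclic shift."""
    img = np.zeros((hp, wp), dtype=np.int64)
    cnt = 0
    for hs in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
        for vs in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
            img[hs, vs] = cnt
            cnt += 1
    win = img.reshape(hp // ws, ws, wp // ws, ws).transpose(0, 2, 1, 3).reshape(-1, ws * ws)
    diff = win[:, :, None] != win[:, None, :]
    return np.where(diff, np.float32(-100.0), np.float32(0.0))


class WindowAttention(Module):
    """Multi-head self-attention inside one window, with relative position
    bias."""

    def __init__(self, dim: int, heads: int, ws: int, rng: np.random.Generator):
        from .autograd import Parameter

        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.bias_table = Parameter(
            rng.normal(0.0, 0.02, size=((2 * ws - 1) ** 2, heads)).astype(np.float32)
        )
        self.heads = heads
        self.dim = dim
        self.ws = ws
        self._bias_index = _relative_position_index(ws)

    def __call__(self, xw: Tensor, mask: np.ndarray | None = None) -> Tensor:
        bw_, t, c = xw.shape
        h = self.heads
        dh = c // h
        qkv = self.qkv(xw).reshape(bw_, t, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (Bw, heads, T, dh)
        attn = (q * np.float32(dh**-0.5)) @ k.transpose(0, 1, 3, 2)
        bias = self.bias_table.take(self._bias_index)  # (T, T, heads)
        attn = attn + bias.transpose(2, 0, 1)
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape(bw_ // nw, nw, h, t, t) + Tensor(mask[None, :, None])
            attn = attn.reshape(bw_, h, t, t)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(bw_, t, c)
        return self.proj(out)


def apply_window_attention(
    x: Tensor, attn: WindowAttention, window_size: int, shift: bool
) -> Tensor:
    """Windowed (optionally shifted) attention over a (B, H, W, C) map.

    Pads H and W up to multiples of ``window_size``, cyclically shifts by
    ``window_size // 2`` when requested (masking attention across the
    wrap-around seam), and crops back, so output shape equals input shape.
    """
    b, h, w, c = x.shape
    ws = window_size
    # padding can cover a fractional last window, but a window that dwarfs
    # the feature map altogether is a configuration error
    if ws > 2 * max(h, w):
        raise ValueError(f"window {ws} larger than padded feature map for {h}x{w} input")
    hp = int(np.ceil(h / ws)) * ws
    wp = int(np.ceil(w / ws)) * ws
    if (hp, wp) != (h, w):
        x = x.pad2d((0, hp - h), (0, wp - w), axes=(1, 2))
    s = ws // 2 if shift else 0
    # a shift is meaningless when a single window covers the whole map
    if s and (hp == ws and wp == ws):
        s = 0
    mask = None
    if s:
        x = x.roll((-s, -s), axes=(1, 2))
        mask = _shift_attention_mask(hp, wp, ws, s)
    xw = window_partition(x, ws)
    xw = attn(xw, mask)
    x = window_reverse(xw, ws, b, hp, wp)
    if s:
        x = x.roll((s, s), axes=(1, 2))
    if (hp, wp) != (h, w):
        x = x[:, :h, :w, :]
    return x


class SwinBlock(Module):
    def __init__(
        self,
        dim: int,
        heads: int,
        ws: int,
        shift: bool,
        mlp_ratio: float,
        rng: np.random.Generator,
    ):
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, ws, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)
        self.ws = ws
        self.shift = shift

    def __call__(self, x: Tensor) -> Tensor:
        x = x + apply_window_attention(self.norm1(x), self.attn, self.ws, self.shift)
        return x + self.mlp(self.norm2(x))


class PatchMerging(Module):
    """Halve H and W, double C: 2x2 space-to-depth + LayerNorm + linear."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.norm = LayerNorm(4 * dim)
        self.reduce = Linear(4 * dim, 2 * dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            x = x.pad2d((0, h % 2), (0, w % 2), axes=(1, 2))
            b, h, w, c = x.shape
        x = x.reshape(b, h // 2, 2, w // 2, 2, c)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // 2, w // 2, 4 * c)
        return self.reduce(self.norm(x))


class PatchEmbed(Module):
    def __init__(self, patch: int, c_in: int, dim: int, rng: np.random.Generator):
        self.proj = Linear(patch * patch * c_in, dim, rng)
        self.norm = LayerNorm(dim)
        self.patch = patch

    def __call__(self, x: Tensor) -> Tensor:
        p = self.patch
        b, h, w, c = x.shape
        if h % p or w % p:
            x = x.pad2d((0, (-h) % p), (0, (-w) % p), axes=(1, 2))
            b, h, w, c = x.shape
        x = x.reshape(b, h // p, p, w // p, p, c)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // p, w // p, p * p * c)
        return self.norm(self.proj(x))


class _DecoderLevel(Module):
    def __init__(self, c_in: int, c_skip: int, c_out: int, rng: np.random.Generator):
        self.up = Upsample2x(c_in, c_out, rng)
        self.conv = Conv2d(c_out + c_skip, c_out, 3, rng)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        x = self.up(x)
        # padding in the encoder can leave the upsampled map one pixel large
        if x.shape[1] != skip.shape[1] or x.shape[2] != skip.shape[2]:
            x = x[:, : skip.shape[1], : skip.shape[2], :]
        return self.conv(concat([x, skip], axis=-1)).relu()


class SwinUNETR2D(Module):
    """The full encoder-decoder landmark network.

    Input: standardized images ``(B, H, W)``; output: 12-channel map
    ``(B, 12, H, W)`` at input resolution, mask channels as raw logits.
    """

    def __init__(self, config: NetConfig | None = None):
        self.config = config or NetConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        dims = [cfg.embed_dim * 2**s for s in range(4)]
        self.patch_embed = PatchEmbed(cfg.patch_size, cfg.in_channels, dims[0], rng)
        self.stages = []
        self.merges = []
        for s in range(4):
            blocks = [
                SwinBlock(dims[s], cfg.num_heads[s], cfg.window_size, bool(i % 2), cfg.mlp_ratio, rng)
                for i in range(cfg.depths[s])
            ]
            self.stages.append(blocks)
            if s < 3:
                self.merges.append(PatchMerging(dims[s], rng))
        self.dec3 = _DecoderLevel(dims[3], dims[2], dims[2], rng)
        self.dec2 = _DecoderLevel(dims[2], dims[1], dims[1], rng)
        self.dec1 = _DecoderLevel(dims[1], dims[0], dims[0], rng)
        self.head_up = Upsample2x(dims[0], dims[0], rng)
        self.head_conv = Conv2d(dims[0], dims[0], 3, rng)
        self.head_out = Linear(dims[0], cfg.out_channels, rng)

    def __call__(self, images: np.ndarray | Tensor) -> Tensor:
        x = images if isinstance(images, Tensor) else Tensor(images)
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        b, h, w = x.shape
        if h < self.config.total_downsampling or w < self.config.total_downsampling:
            raise ValueError(
                f"input {h}x{w} smaller than the total downsampling factor "
                f"{self.config.total_downsampling}"
            )
        x = x.reshape(b, h, w, 1)
        x = self.patch_embed(x)
        skips = []
        for s in range(4):
            for block in self.stages[s]:
                x = block(x)
            if s < 3:
                skips.append(x)
                x = self.merges[s](x)
        x = self.dec3(x, skips[2])
        x = self.dec2(x, skips[1])
        x = self.dec1(x, skips[0])
        x = self.head_up(x)
        if x.shape[1] != h or x.shape[2] != w:
            x = x[:, :h, :w, :]
        x = self.head_conv(x).relu()
        x = self.head_out(x)
        return x.transpose(0, 3, 1, 2)  # (B, 12, H, W)

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint with the config embedded."""
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "SwinUNETR2D":
        with np.load(path) as z:
            raw = json.loads(bytes(z["__config__"].tobytes()).decode())
            raw["depths"] = tuple(raw["depths"])
            raw["num_heads"] = tuple(raw["num_heads"])
            model = cls(NetConfig(**raw))
            model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return model
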