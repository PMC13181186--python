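"""Hierarchical shifted-window transformer encoder.

The backbone tokenises the image into non-overlapping patches, runs stacks of
window-local multi-head self-attention blocks (alternating between aligned and
cyclically shifted window grids so information crosses window borders), and
downsamples between stages by merging 2x2 neighbourhoods.  The result is a
three-level feature pyramid at strides 4/8/16 relative to the input (or, for
the 32x-downsampling ablation variant, an internal fourth stage whose deepest
three levels are exposed at strides 8/16/32).

Windows that overhang a stage's spatial extent are zero-padded on the
right/bottom and the padded tokens are masked out of attention, so window
sizes need not divide the feature-map extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Module, Parameter, Tensor


class ConfigError(ValueError):
    """Invalid model/module configuration."""


class DimensionError(ValueError):
    """Input dimensions violate a divisibility or compatibility contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureMap:
    """A (batch, channel, row, col) activation with its stride annotation.

    ``stride`` is the number of input pixels per feature cell.
    """

    data: Tensor
    stride: int

    @property
    def shape(self):
        return self.data.shape

    @property
    def channels(self) -> int:
        return self.data.shape[1]


@dataclass
class EncoderConfig:
    """Backbone hyperparameters.

    The default is the desk-scale preset (small enough for CPU test runs);
    :meth:`full` gives the full-size preset used for 224x224 inputs.
    """

    patch_size: int = 4
    embed_dim: int = 24
    depths: tuple[int, ...] = (2, 2, 2)
    num_heads: tuple[int, ...] = (2, 4, 8)
    window_size: int = 4
    downsample_factor: int = 16
    mlp_ratio: float = 4.0
    seed: int = 0

    @classmethod
    def full(cls, seed: int = 0) -> "EncoderConfig":
        return cls(patch_size=4, embed_dim=96, depths=(2, 2, 6),
                   num_heads=(3, 6, 12), window_size=7, seed=seed)

    def validate(self) -> None:
        if len(self.depths) != len(self.num_heads):
            raise ConfigError("depths and num_heads must have equal length")
        if self.downsample_factor not in (16, 32):
            raise ConfigError("downsample_factor must be 16 or 32")
        for i, h in enumerate(self.num_heads):
            if (self.embed_dim * 2 ** i) % h:
                raise ConfigError(
                    f"stage {i}: {self.embed_dim * 2 ** i} channels not "
                    f"divisible by {h} heads")

    @property
    def n_stages(self) -> int:
        # number of pyramid levels from patch stride to downsample_factor
        n = 1
        s = self.patch_size
        while s < self.downsample_factor:
            s *= 2
            n += 1
        return n

    def stage_plan(self) -> list[tuple[int, int, int]]:
        """(depth, heads, channels) per stage; a 4th stage for the 32x
        variant extends the deepest entry with doubled heads."""
        depths, heads = list(self.depths), list(self.num_heads)
        while len(depths) < self.n_stages:
            depths.append(depths[-1])
            heads.append(heads[-1] * 2)
        return [(depths[i], heads[i], self.embed_dim * 2 ** i)
                for i in range(self.n_stages)]


# ---------------------------------------------------------------------------
# patch embedding
# ---------------------------------------------------------------------------


class PatchEmbed(Module):
    """Linear projection of non-overlapping patches + layer normalisation."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        p = config.patch_size
        self.patch_size = p
        self.proj = nn.Linear(3 * p * p, config.embed_dim, rng)
        self.norm = nn.LayerNorm(config.embed_dim)

    def forward(self, images: Tensor) -> Tensor:
        B, C, H, W = images.shape
        p = self.patch_size
        for axis, extent in (("height", H), ("width", W)):
            if extent % p:
                raise DimensionError(
                    f"{axis} {extent} not divisible by patch_size {p}")
        h, w = H // p, W // p
        x = images.reshape(B, C, h, p, w, p)
        x = x.transpose(0, 2, 4, 1, 3, 5).reshape(B, h, w, C * p * p)
        x = self.norm(self.proj(x))                       # (B, h, w, C0)
        return x.transpose(0, 3, 1, 2)                    # NCHW


def patch_embed(images: "ImageBatchLike", config: EncoderConfig) -> FeatureMap:
    """Functional patch embedding with a config-seeded projection."""
    rng = np.random.default_rng(config.seed)
    emb = PatchEmbed(config, rng)
    x = images.data if isinstance(images, FeatureMap) else Tensor._lift(images)
    return FeatureMap(emb(x), stride=config.patch_size)


ImageBatchLike = Tensor  # rank-4 (B, 3, H, W) array in [0, 1]


# ---------------------------------------------------------------------------
# window attention
# ---------------------------------------------------------------------------


def _window_partition(x: Tensor, ws: int) -> Tensor:
    """NCHW -> (B * n_windows, ws*ws, C) in row-major window order."""
    B, C, H, W = x.shape
    nh, nw = H // ws, W // ws
    x = x.reshape(B, C, nh, ws, nw, ws)
    x = x.transpose(0, 2, 4, 3, 5, 1)                     # B nh nw ws ws C
    return x.reshape(B * nh * nw, ws * ws, C)


def _window_reverse(win: Tensor, ws: int, B: int, C: int, H: int, W: int) -> Tensor:
    nh, nw = H // ws, W // ws
    x = win.reshape(B, nh, nw, ws, ws, C)
    x = x.transpose(0, 5, 1, 3, 2, 4)
    return x.reshape(B, C, H, W)


def _relative_position_index(ws: int) -> np.ndarray:
    coords = np.stack(np.meshgrid(np.arange(ws), np.arange(ws),
                                  indexing="ij")).reshape(2, -1)
    rel = coords[:, :, None] - coords[:, None, :]         # (2, N, N)
    rel = rel + (ws - 1)
    return (rel[0] * (2 * ws - 1) + rel[1]).astype(np.int64)


def _shift_region_ids(Hp: int, Wp: int, ws: int, shift: int) -> np.ndarray:
    """Swin-style region labels: tokens from different pre-roll regions must
    not attend to each other inside a shifted window."""
    ids = np.zeros((Hp, Wp), dtype=np.int64)
    cnt = 0
    h_slices = (slice(0, -ws), slice(-ws, -shift), slice(-shift, None))
    w_slices = (slice(0, -ws), slice(-ws, -shift), slice(-shift, None))
    for hs in h_slices:
        for vs in w_slices:
            ids[hs, vs] = cnt
            cnt += 1
    return ids


_NEG = -1e9  # additive mask value; large but exp-safe in float32 softmax


class WindowAttention(Module):
    """Multi-head self-attention inside ws x ws windows with a learned
    relative-position bias (zero-initialised)."""

    def __init__(self, dim: int, num_heads: int, window_size: int,
                 rng: np.random.Generator):
        super().__init__()
        if dim % num_heads:
            raise ConfigError(f"{dim} channels not divisible by {num_heads} heads")
        self.dim = dim
        self.num_heads = num_heads
        self.window_size = window_size
        self.scale = (dim // num_heads) ** -0.5
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.rel_bias = Parameter(
            np.zeros(((2 * window_size - 1) ** 2, num_heads)))
        self._rel_index = _relative_position_index(window_size)

    def attend(self, windows: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """windows: (Bw, N, C); mask: (n_windows, N, N) additive, broadcast
        over the batch groups of windows."""
        Bw, N, C = windows.shape
        H, hd = self.num_heads, C // self.num_heads
        qkv = self.qkv(windows).reshape(Bw, N, 3, H, hd)
        qkv = qkv.transpose(2, 0, 3, 1, 4)                # 3, Bw, H, N, hd
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale  # Bw H N N
        bias = self.rel_bias[self._rel_index.reshape(-1)]
        bias = bias.reshape(N, N, H).transpose(2, 0, 1)    # H N N
        attn = attn + bias
        if mask is not None:
            nW = mask.shape[0]
            attn = attn.reshape(Bw // nW, nW, H, N, N)
            attn = attn + Tensor(mask[None, :, None])
            attn = attn.reshape(Bw, H, N, N)
        attn = nn.softmax(attn, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(Bw, N, C)
        return self.proj(out)

    def forward_map(self, x: Tensor, shift: int = 0) -> Tensor:
        """Apply windowed attention to an NCHW map, padding and (optionally)
        cyclically shifting the window grid."""
        B, C, H, W = x.shape
        ws = self.window_size
        if shift not in (0, ws // 2):
            raise ConfigError("shift must be 0 or window_size // 2")
        pb, pr = (-H) % ws, (-W) % ws
        xp = x.pad2d(0, pb, 0, pr) if (pb or pr) else x
        Hp, Wp = H + pb, W + pr

        valid = np.zeros((Hp, Wp), dtype=bool)
        valid[:H, :W] = True
        if shift:
            xp = xp.roll((-shift, -shift))
            valid = np.roll(valid, (-shift, -shift), axis=(0, 1))
            region = _shift_region_ids(Hp, Wp, ws, shift)
            region = np.roll(region, (-shift, -shift), axis=(0, 1))
        else:
            region = np.zeros((Hp, Wp), dtype=np.int64)

        mask = None
        if (pb or pr) or shift:
            nh, nw = Hp // ws, Wp // ws
            reg = region.reshape(nh, ws, nw, ws).transpose(0, 2, 1, 3)
            reg = reg.reshape(nh * nw, ws * ws)
            ok = np.ones((nh * nw, ws * ws), dtype=bool)
            okv = valid.reshape(nh, ws, nw, ws).transpose(0, 2, 1, 3)
            ok &= okv.reshape(nh * nw, ws * ws)
            same = reg[:, :, None] == reg[:, None, :]
            key_ok = ok[:, None, :] & same
            mask = np.where(key_ok, 0.0, _NEG).astype(np.float32)

        win = _window_partition(xp, ws)
        out = self.attend(win, mask)
        out = _window_reverse(out, ws, B, C, Hp, Wp)
        if shift:
            out = out.roll((shift, shift))
        if pb or pr:
            out = out[:, :, :H, :W]
        return out


def window_self_attention(x: FeatureMap, window_size: int, num_heads: int,
                          shift: int = 0, seed: int = 0) -> FeatureMap:
    """Functional windowed self-attention with seed-initialised weights."""
    rng = np.random.default_rng(seed)
    wa = WindowAttention(x.channels, num_heads, window_size, rng)
    return FeatureMap(wa.forward_map(x.data, shift), stride=x.stride)


# ---------------------------------------------------------------------------
# transformer block and patch merging
# ---------------------------------------------------------------------------


def _gelu(x: Tensor) -> Tensor:
    # sigmoid-weighted linear approximation of GELU
    return x * nn.sigmoid(x * 1.702)


class SwinBlock(Module):
    """Pre-norm window-attention block: LN -> W-MSA -> +res, LN -> MLP -> +res."""

    def __init__(self, dim: int, num_heads: int, window_size: int, shift: int,
                 mlp_ratio: float, rng: np.random.Generator):
        super().__init__()
        self.shift = shift
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, num_heads, window_size, rng)
        self.norm2 = nn.LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        t = x.transpose(0, 2, 3, 1)                       # NHWC tokens
        h = self.norm1(t).transpose(0, 3, 1, 2)
        x = x + self.attn.forward_map(h, self.shift)
        t = x.transpose(0, 2, 3, 1)
        m = self.fc2(_gelu(self.fc1(self.norm2(t))))
        return x + m.transpose(0, 3, 1, 2)


class PatchMerging(Module):
    """2x2 neighbourhood concat + linear reduction: halves h,w; doubles C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm = nn.LayerNorm(4 * dim)
        self.reduce = nn.Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        for axis, extent in (("height", H), ("width", W)):
            if extent % 2:
                raise DimensionError(f"{axis} {extent} is odd; cannot merge 2x2")
        x = x.reshape(B, C, H // 2, 2, W // 2, 2)
        x = x.transpose(0, 2, 4, 3, 5, 1)                 # B h w 2 2 C
        x = x.reshape(B, H // 2, W // 2, 4 * C)
        x = self.reduce(self.norm(x))
        return x.transpose(0, 3, 1, 2)


def patch_merging(x: FeatureMap, seed: int = 0) -> FeatureMap:
    rng = np.random.default_rng(seed)
    pm = PatchMerging(x.channels, rng)
    return FeatureMap(pm(x.data), stride=x.stride * 2)


# ---------------------------------------------------------------------------
# full encoder
# ---------------------------------------------------------------------------


class SwinEncoder(Module):
    """Patch embedding + per-stage block stacks with patch merging between.

    ``forward`` returns the exposed pyramid: the three deepest stages, which
    for the default 16x configuration are strides 4/8/16 with channel counts
    C0 / 2*C0 / 4*C0.
    """

    def __init__(self, config: EncoderConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        config.validate()
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.embed = PatchEmbed(config, rng)
        self.stages: list[list[SwinBlock]] = []
        self.merges: list[PatchMerging] = []
        ws = config.window_size
        for i, (depth, heads, dim) in enumerate(config.stage_plan()):
            blocks = [
                SwinBlock(dim, heads, ws, 0 if d % 2 == 0 else ws // 2,
                          config.mlp_ratio, rng)
                for d in range(depth)
            ]
            self.stages.append(blocks)
            if i + 1 < config.n_stages:
                self.merges.append(PatchMerging(dim, rng))

    def _check_dims(self, images: Tensor) -> None:
        need = self.config.patch_size * 2 ** (self.config.n_stages - 1)
        B, C, H, W = images.shape
        for axis, extent in (("height", H), ("width", W)):
            if extent % need:
                raise DimensionError(
                    f"{axis} {extent} not divisible by {need} "
                    f"(patch_size x 2^(n_stages-1))")

    def forward(self, images: Tensor) -> list[FeatureMap]:
        self._check_dims(images)
        x = self.embed(images)
        stride = self.config.patch_size
        pyramid: list[FeatureMap] = []
        for i, blocks in enumerate(self.stages):
            for blk in blocks:
                x = blk(x)
            pyramid.append(FeatureMap(x, stride))
            if i < len(self.merges):
                x = self.merges[i](x)
                stride *= 2
        return pyramid[-3:]


def encode(images: Tensor, config: EncoderConfig) -> list[FeatureMap]:
    """Build a seed-initialised encoder and run it (deterministic per seed)."""
    return SwinEncoder(config)(Tensor._lift(images))
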