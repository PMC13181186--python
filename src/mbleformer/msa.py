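"""Multi-scale attention: four-branch importance estimation.

Each encoder stage's feature map is re-weighted by an attention map built
from four views of the same features:

* key-pixel view      — 3x3 convolution, dilation 1
* surrounding view    — 3x3 convolution, dilation 2
* horizontal view     — per-row average pooling (one value per row)
* vertical view       — per-column average pooling (one value per column)

The two convolutional branches are concatenated channel-wise (C -> 2C),
passed through a shared 1x1 convolution + batch norm + nonlinearity that
keeps the channel count, then split back; each half gets its own 1x1
convolution and sigmoid, giving importance maps za1 (key pixels) and za2
(surroundings) in (0,1).  The two pooled branches follow the same
concat -> reduce -> split pattern along the pooled axis, yielding row and
column importance profiles yh and yw.  The four maps are fused (arithmetic
mean by default, elementwise product as a config switch) and multiplied into
the input, so the module only ever attenuates: the fused weight lies in
(0,1).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Module, Tensor
from .encoder import ConfigError, FeatureMap


def directional_pool(x: Tensor | FeatureMap) -> tuple[Tensor, Tensor]:
    """Row profile (B,C,h,1) and column profile (B,C,1,w) by averaging."""
    t = x.data if isinstance(x, FeatureMap) else Tensor._lift(x)
    ph = t.mean(axis=3, keepdims=True)
    pw = t.mean(axis=2, keepdims=True)
    return ph, pw


def combine_maps(x: Tensor, maps: list[Tensor], fusion: str = "mean") -> Tensor:
    """Fuse the four importance maps and re-weight ``x``."""
    if fusion == "mean":
        a = maps[0]
        for m in maps[1:]:
            a = a + m
        a = a * (1.0 / len(maps))
    elif fusion == "product":
        a = maps[0]
        for m in maps[1:]:
            a = a * m
    else:
        raise ConfigError(f"unknown msa fusion {fusion!r}")
    return x * a


def _activation(name: str):
    if name == "relu":
        return nn.relu
    if name == "sigmoid":
        return nn.sigmoid
    raise ConfigError(f"unknown msa activation {name!r}")


class MSA(Module):
    """Four-branch multi-scale attention over a (B, C, h, w) feature map."""

    def __init__(self, channels: int, fusion: str = "mean",
                 activation: str = "relu",
                 rng: np.random.Generator | None = None, seed: int = 0):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(seed)
        if fusion not in ("mean", "product"):
            raise ConfigError(f"unknown msa fusion {fusion!r}")
        self.channels = channels
        self.fusion = fusion
        self.act = _activation(activation)
        # local (convolutional) branches
        self.conv_d1 = nn.Conv2d(channels, channels, 3, rng, dilation=1)
        self.conv_d2 = nn.Conv2d(channels, channels, 3, rng, dilation=2)
        self.local_reduce = nn.Conv2d(2 * channels, 2 * channels, 1, rng)
        self.local_norm = nn.BatchNorm2d(2 * channels)
        self.imp1 = nn.Conv2d(channels, channels, 1, rng)
        self.imp2 = nn.Conv2d(channels, channels, 1, rng)
        # directional (pooled) branches
        self.dir_reduce = nn.Conv2d(channels, channels, 1, rng)
        self.dir_norm = nn.BatchNorm2d(channels)
        self.imp_h = nn.Conv2d(channels, channels, 1, rng)
        self.imp_w = nn.Conv2d(channels, channels, 1, rng)
        # open-gate init: sigmoid(+2) ~ 0.88, so the module starts close to
        # an identity re-weighting and learns to close gates where needed
        for gate in (self.imp1, self.imp2, self.imp_h, self.imp_w):
            gate.bias.data[:] = 2.0

    # -- branch operations -------------------------------------------------

    def local_scale_features(self, x: Tensor,
                             pad_mode: str = "zeros") -> tuple[Tensor, Tensor]:
        """Dilation-1 and dilation-2 3x3 features, same spatial dims."""
        return self.conv_d1(x, pad_mode), self.conv_d2(x, pad_mode)

    def fuse_reduce_split(self, a: Tensor, b: Tensor) -> tuple[Tensor, Tensor]:
        """Channel concat to 2C, 1x1 conv + norm + activation, split back."""
        if a.shape != b.shape:
            raise ConfigError(f"branch shapes differ: {a.shape} vs {b.shape}")
        z = nn.concat([a, b], axis=1)
        z = self.act(self.local_norm(self.local_reduce(z)))
        c = self.channels
        return z[:, :c], z[:, c:]

    def importance_map(self, f: Tensor, which: str) -> Tensor:
        conv = {"za1": self.imp1, "za2": self.imp2,
                "yh": self.imp_h, "yw": self.imp_w}[which]
        return nn.sigmoid(conv(f))

    def directional_maps(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Pooled row/column profiles -> shared reduce -> per-axis sigmoids."""
        ph, pw = directional_pool(x)
        h = ph.shape[2]
        stacked = nn.concat([ph, pw.transpose(0, 1, 3, 2)], axis=2)
        stacked = self.act(self.dir_norm(self.dir_reduce(stacked)))
        rh = stacked[:, :, :h]
        rw = stacked[:, :, h:].transpose(0, 1, 3, 2)
        return self.importance_map(rh, "yh"), self.importance_map(rw, "yw")

    # -- full module ---------------------------------------------------------

    def attention_maps(self, x: Tensor,
                       pad_mode: str = "zeros") -> list[Tensor]:
        f1, f2 = self.local_scale_features(x, pad_mode)
        g1, g2 = self.fuse_reduce_split(f1, f2)
        za1 = self.importance_map(g1, "za1")
        za2 = self.importance_map(g2, "za2")
        yh, yw = self.directional_maps(x)
        B, C, h, w = x.shape
        ones = Tensor(np.ones((1, 1, h, w), dtype=np.float32))
        return [za1, za2, yh * ones, yw * ones]   # broadcast profiles to h x w

    def forward(self, x: Tensor | FeatureMap,
                pad_mode: str = "zeros") -> Tensor | FeatureMap:
        if isinstance(x, FeatureMap):
            return FeatureMap(self.forward(x.data, pad_mode), x.stride)
        maps = self.attention_maps(x, pad_mode)
        return combine_maps(x, maps, self.fusion)


def msa_apply(x: FeatureMap, fusion: str = "mean", seed: int = 0) -> FeatureMap:
    """Functional form: build a seeded module and apply it."""
    return MSA(x.channels, fusion=fusion, seed=seed)(x)
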