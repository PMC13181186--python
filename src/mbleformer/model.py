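"""Full network assembly: encoder + 3 MSA + 2 BLEU + segmentation head.

Data flow for the default 16x-downsampling configuration:

    image (B,3,H,W)
      -> encoder -> pyramid [stride 4 (C0), stride 8 (2C0), stride 16 (4C0)]
      -> one MSA per stage (identity when ablated)
      -> BLEU-1: x1 = stride-8 map, x2 = stride-16 map  -> stride-8 output
      -> BLEU-2: x1 = stride-4 map, x2 = BLEU-1 output  -> stride-4 output
      -> head: bilinear upsample to input resolution, 3x3 conv + ReLU,
         1x1 conv -> single-channel logit map (B,1,H,W)

Ablation switches replace the MSA modules with identities and/or the BLEU
steps with a plain upsample-concat-convolve fusion, so each module's
contribution can be measured in isolation.  Binary masks come from thresholding the sigmoid
of the logits (>= threshold -> lesion).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Module, Tensor
from .bleu import BLEU, BLEUConfig, FusionPair
from .encoder import ConfigError, EncoderConfig, FeatureMap, SwinEncoder
from .msa import MSA

CHECKPOINT_FORMAT = 1


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    bleu: BLEUConfig = field(default_factory=BLEUConfig)
    msa_fusion: str = "mean"
    msa_activation: str = "relu"
    head_channels: int = 16
    predict_threshold: float = 0.5
    use_msa: bool = True
    use_bleu: bool = True
    seed: int = 0

    def validate(self) -> None:
        self.encoder.validate()
        self.bleu.validate()
        if not 0.0 < self.predict_threshold < 1.0:
            raise ConfigError("predict_threshold must lie in (0,1)")
        if self.head_channels < 1:
            raise ConfigError("head_channels must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder"]["depths"] = list(self.encoder.depths)
        d["encoder"]["num_heads"] = list(self.encoder.num_heads)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        enc = dict(d["encoder"])
        enc["depths"] = tuple(enc["depths"])
        enc["num_heads"] = tuple(enc["num_heads"])
        return cls(encoder=EncoderConfig(**enc), bleu=BLEUConfig(**d["bleu"]),
                   **{k: v for k, v in d.items()
                      if k not in ("encoder", "bleu")})


class _PlainFuse(Module):
    """Ablation decoder step: upsample, project, concat, 3x3 convolve."""

    def __init__(self, c1: int, c2: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Conv2d(c2, c1, 1, rng)
        self.mix = nn.Conv2d(2 * c1, c1, 3, rng)

    def forward(self, pair: FusionPair) -> FeatureMap:
        up = nn.bilinear_upsample(pair.x2.data, 2)
        up = self.proj(up)
        out = self.mix(nn.concat([pair.x1.data, up], axis=1))
        return FeatureMap(out, pair.x1.stride)


class _Identity(Module):
    def forward(self, x):
        return x


class MBLEformer(Module):
    """The segmentation network; see the module docstring for wiring."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = SwinEncoder(config.encoder, rng)
        plan = config.encoder.stage_plan()[-3:]
        chans = [c for _, _, c in plan]                  # shallow -> deep
        if config.use_msa:
            self.msa = [MSA(c, config.msa_fusion, config.msa_activation,
                            rng=rng) for c in chans]
        else:
            self.msa = [_Identity() for _ in chans]
        if config.use_bleu:
            self.fuse1 = BLEU(chans[1], chans[2], config.bleu, rng=rng)
            self.fuse2 = BLEU(chans[0], chans[1], config.bleu, rng=rng)
        else:
            self.fuse1 = _PlainFuse(chans[1], chans[2], rng)
            self.fuse2 = _PlainFuse(chans[0], chans[1], rng)
        self.head_conv = nn.Conv2d(chans[0], config.head_channels, 3, rng)
        self.head_out = nn.Conv2d(config.head_channels, 1, 1, rng)

    def forward(self, images: Tensor | np.ndarray) -> Tensor:
        x = Tensor._lift(images)
        stages = self.encoder(x)
        stages = [m(s) for m, s in zip(self.msa, stages)]
        mid = self.fuse1(FusionPair(stages[1], stages[2]))
        top = self.fuse2(FusionPair(stages[0], mid))
        up = nn.bilinear_upsample(top.data, top.stride)
        h = nn.relu(self.head_conv(up))
        return self.head_out(h)

    def predict_proba(self, images) -> np.ndarray:
        was_training = self.training
        self.eval()
        logits = self.forward(images)
        if was_training:
            self.train()
        return 1.0 / (1.0 + np.exp(-logits.data[:, 0]))

    def predict_mask(self, images, threshold: float | None = None) -> np.ndarray:
        thr = self.config.predict_threshold if threshold is None else threshold
        if not 0.0 < thr < 1.0:
            raise ConfigError("threshold must lie in (0,1)")
        return (self.predict_proba(images) >= thr).astype(np.uint8)


def build_mbleformer(config: ModelConfig | None = None) -> MBLEformer:
    """Build a deterministically seed-initialised model."""
    return MBLEformer(config if config is not None else ModelConfig())


def predict_mask(model: MBLEformer, images, threshold: float = 0.5) -> np.ndarray:
    return model.predict_mask(images, threshold)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: MBLEformer, path: str | Path,
                    meta: dict | None = None) -> None:
    """Single-file checkpoint: parameters + config + metadata."""
    header = {
        "format": CHECKPOINT_FORMAT,
        "config": model.config.to_dict(),
        "meta": meta or {},
    }
    state = model.state_dict()
    np.savez(path, __header__=np.array(json.dumps(header)), **state)


def load_checkpoint(path: str | Path) -> MBLEformer:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["__header__"]))
        if header["format"] != CHECKPOINT_FORMAT:
            raise ValueError(f"unsupported checkpoint format {header['format']}")
        config = ModelConfig.from_dict(header["config"])
        model = MBLEformer(config)
        state = {k: data[k] for k in data.files if k != "__header__"}
    model.load_state_dict(state)
    return model
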