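"""Flat-key YAML configuration for the CLI.

The config document is a single mapping with dotted keys mirroring every
design-decision switch, e.g.::

    encoder.embed_dim: 24
    msa.fusion: mean
    bleu.alpha: 0.6
    bleu.midband: pass
    train.epochs: 20

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path

import yaml

from .encoder import ConfigError, EncoderConfig
from .bleu import BLEUConfig
from .model import ModelConfig
from .train import TrainConfig

_MODEL_KEYS = ("msa_fusion", "msa_activation", "head_channels",
               "predict_threshold", "use_msa", "use_bleu", "seed")


def default_configs() -> tuple[ModelConfig, TrainConfig]:
    return ModelConfig(), TrainConfig()


def flatten(model: ModelConfig, train: TrainConfig) -> dict:
    out: dict = {}
    for f in fields(model.encoder):
        v = getattr(model.encoder, f.name)
        out[f"encoder.{f.name}"] = list(v) if isinstance(v, tuple) else v
    for f in fields(model.bleu):
        out[f"bleu.{f.name}"] = getattr(model.bleu, f.name)
    out["msa.fusion"] = model.msa_fusion
    out["msa.activation"] = model.msa_activation
    for key in ("head_channels", "predict_threshold", "use_msa",
                "use_bleu", "seed"):
        out[f"model.{key}"] = getattr(model, key)
    for f in fields(train):
        out[f"train.{f.name}"] = getattr(train, f.name)
    return out


def unflatten(doc: dict) -> tuple[ModelConfig, TrainConfig]:
    model, train = default_configs()
    enc_kw, bleu_kw, model_kw, train_kw = {}, {}, {}, {}
    enc_fields = {f.name for f in fields(EncoderConfig)}
    bleu_fields = {f.name for f in fields(BLEUConfig)}
    train_fields = {f.name for f in fields(TrainConfig)}
    for key, value in (doc or {}).items():
        scope, _, name = key.partition(".")
        if scope == "encoder" and name in enc_fields:
            if name in ("depths", "num_heads"):
                value = tuple(value)
            enc_kw[name] = value
        elif scope == "bleu" and name in bleu_fields:
            bleu_kw[name] = value
        elif scope == "msa" and name in ("fusion", "activation"):
            model_kw[f"msa_{name}"] = value
        elif scope == "model" and name in _MODEL_KEYS:
            model_kw[name] = value
        elif scope == "train" and name in train_fields:
            train_kw[name] = value
        else:
            raise ConfigError(f"unknown config key {key!r}")
    model.encoder = replace(model.encoder, **enc_kw)
    model.bleu = replace(model.bleu, **bleu_kw)
    for k, v in model_kw.items():
        setattr(model, k, v)
    train = replace(train, **train_kw)
    model.validate()
    train.validate()
    return model, train


def load_config(path: str | Path | None) -> tuple[ModelConfig, TrainConfig]:
    if path is None:
        return default_configs()
    doc = yaml.safe_load(Path(path).read_text())
    return unflatten(doc or {})


def save_config(path: str | Path, model: ModelConfig,
                train: TrainConfig) -> None:
    Path(path).write_text(
        yaml.safe_dump(flatten(model, train), sort_keys=True))
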