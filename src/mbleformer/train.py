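"""Training and evaluation pipeline.

Recipe: Adam, initial learning rate 1e-4 multiplied by 0.1 every 40 epochs,
batch size 8, Dice+BCE objective, 150 epochs at 224x224 for the full-scale
configuration (desk-scale runs override epochs/size/batch).  Augmentation
applies, each with probability 0.3: random rotation (+/-30 deg, image
bilinear / mask nearest, reflect padding), horizontal flip, vertical flip,
and coarse dropout (up to 4 rectangles, each side <= 10% of the image,
filled with the image's mean colour, image only — dropout models occlusion,
not label change).

Checkpoint selection uses the best validation mIoU; the held-out split of the
9:1 division serves as both validation and test set (a known leakage caveat
at benchmark scale).  Everything — data order, augmentation, initialisation —
is seeded; model initialisation is governed by the model seed and the sample
stream by the training seed, independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .metrics import (ConfusionCounts, MetricReport, confusion_counts,
                      dice_bce_loss, metric_report)
from .model import MBLEformer, ModelConfig, build_mbleformer, save_checkpoint
from .synth import LabeledSample, load_samples


@dataclass
class TrainConfig:
    lr0: float = 1e-4
    lr_decay: float = 0.1
    lr_decay_every: int = 40
    batch_size: int = 8
    epochs: int = 150
    input_size: int = 224
    aug_prob: float = 0.3
    rotation_range: float = 30.0
    dropout_max_boxes: int = 4
    dropout_max_frac: float = 0.10
    seed: int = 0
    threshold: float = 0.5
    early_stop_miou: float | None = None   # stop once validation reaches this

    def validate(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not 0.0 <= self.aug_prob <= 1.0:
            raise ValueError("aug_prob must lie in [0, 1]")


@dataclass
class EpochRecord:
    epoch: int
    loss: float
    lr: float
    metrics: MetricReport


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1
    best_miou: float = -1.0

    def write_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for r in self.records:
                fh.write(json.dumps({"epoch": r.epoch, "loss": r.loss,
                                     "lr": r.lr,
                                     **r.metrics.to_dict()}) + "\n")


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Step schedule: lr0 * decay^(epoch // decay_every)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.lr0 * config.lr_decay ** (epoch // config.lr_decay_every)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def hflip(sample: LabeledSample) -> LabeledSample:
    return LabeledSample(sample.image[:, ::-1].copy(),
                         sample.mask[:, ::-1].copy(), sample.seed)


def vflip(sample: LabeledSample) -> LabeledSample:
    return LabeledSample(sample.image[::-1].copy(),
                         sample.mask[::-1].copy(), sample.seed)


def rotate_sample(sample: LabeledSample, angle: float) -> LabeledSample:
    img = ndimage.rotate(sample.image, angle, axes=(1, 0), reshape=False,
                         order=1, mode="reflect")
    msk = ndimage.rotate(sample.mask, angle, reshape=False,
                         order=0, mode="reflect")
    return LabeledSample(np.clip(img, 0, 255).astype(sample.image.dtype),
                         msk.astype(sample.mask.dtype), sample.seed)


def coarse_dropout(sample: LabeledSample, rng: np.random.Generator,
                   max_boxes: int = 4, max_frac: float = 0.10) -> LabeledSample:
    """Blank up to ``max_boxes`` rectangles with the image mean colour.

    Image only: the mask is left untouched."""
    img = sample.image.copy()
    H, W = img.shape[:2]
    fill = img.reshape(-1, img.shape[-1]).mean(axis=0)
    for _ in range(int(rng.integers(1, max_boxes + 1))):
        bh = int(rng.integers(1, max(2, int(H * max_frac)) + 1))
        bw = int(rng.integers(1, max(2, int(W * max_frac)) + 1))
        r = int(rng.integers(0, H - bh + 1))
        c = int(rng.integers(0, W - bw + 1))
        img[r:r + bh, c:c + bw] = fill.astype(img.dtype)
    return LabeledSample(img, sample.mask, sample.seed)


def augment(sample: LabeledSample, rng: np.random.Generator,
            config: TrainConfig | None = None) -> LabeledSample:
    """Apply each of the four transforms independently with prob aug_prob."""
    cfg = config if config is not None else TrainConfig()
    p = cfg.aug_prob
    if rng.uniform() < p:
        sample = rotate_sample(
            sample, float(rng.uniform(-cfg.rotation_range, cfg.rotation_range)))
    if rng.uniform() < p:
        sample = hflip(sample)
    if rng.uniform() < p:
        sample = vflip(sample)
    if rng.uniform() < p:
        sample = coarse_dropout(sample, rng, cfg.dropout_max_boxes,
                                cfg.dropout_max_frac)
    return sample


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------


def _to_batch(samples: list[LabeledSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    x = x.transpose(0, 3, 1, 2)
    y = np.stack([s.mask for s in samples]).astype(np.float32)[:, None]
    return x, y


def _resolve_split(data, split: str) -> list[LabeledSample]:
    if isinstance(data, (str, Path)):
        return load_samples(data, split=split)
    raise TypeError("data must be a manifest path or explicit sample lists")


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def train(model: MBLEformer, data, config: TrainConfig,
          checkpoint_path: str | Path | None = None,
          log_path: str | Path | None = None,
          val_data: list[LabeledSample] | None = None,
          ) -> tuple[dict[str, np.ndarray], TrainHistory]:
    """Train in place; returns (best-mIoU parameter state, history).

    ``data`` is either a manifest path (train/test splits are read from it)
    or a list of LabeledSample used for training, in which case ``val_data``
    supplies the validation samples.
    """
    config.validate()
    if isinstance(data, (str, Path)):
        train_samples = _resolve_split(data, "train")
        val_samples = _resolve_split(data, "test")
    else:
        train_samples = list(data)
        val_samples = list(val_data) if val_data is not None else []
    if not train_samples:
        raise ValueError("empty training split")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr0)
    history = TrainHistory()
    best_state = model.state_dict()

    for epoch in range(config.epochs):
        lr = lr_at_epoch(epoch, config)
        opt.lr = lr
        model.train()
        order = rng.permutation(len(train_samples))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch_ids = order[start:start + config.batch_size]
            batch = [augment(train_samples[i], rng, config)
                     for i in batch_ids]
            x, y = _to_batch(batch)
            logits = model(x)
            p = nn.sigmoid(logits)
            loss = dice_bce_loss(p, y)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.item()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())

        if val_samples:
            report = evaluate(model, val_samples, threshold=config.threshold)
        else:
            report = MetricReport(*([float("nan")] * 7))
        rec = EpochRecord(epoch, float(np.mean(losses)), lr, report)
        history.records.append(rec)
        if val_samples and report.miou > history.best_miou:
            history.best_miou = report.miou
            history.best_epoch = epoch
            best_state = model.state_dict()
        if (config.early_stop_miou is not None and val_samples
                and report.miou >= config.early_stop_miou):
            break

    if not val_samples:
        best_state = model.state_dict()
    if checkpoint_path is not None:
        model.load_state_dict(best_state)
        save_checkpoint(model, checkpoint_path,
                        meta={"seed": config.seed,
                              "best_epoch": history.best_epoch,
                              "best_miou": history.best_miou})
    if log_path is not None:
        history.write_jsonl(log_path)
    return best_state, history


def evaluate(model: MBLEformer, data, threshold: float = 0.5,
             batch_size: int = 8,
             out_json: str | Path | None = None,
             out_csv: str | Path | None = None) -> MetricReport:
    """Pooled (micro) pixel metrics of the model on a sample list/manifest."""
    samples = (_resolve_split(data, "test")
               if isinstance(data, (str, Path)) else list(data))
    if not samples:
        raise ValueError("empty evaluation split")
    counts = ConfusionCounts(0, 0, 0, 0)
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        x, y = _to_batch(chunk)
        pred = model.predict_mask(x, threshold)
        counts = counts + confusion_counts(pred, y[:, 0].astype(np.uint8))
    report = metric_report(counts)
    if out_json is not None:
        report.write_json(out_json)
    if out_csv is not None:
        report.write_csv(out_csv)
    return report


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

MODULE_ABLATIONS: list[tuple[str, dict]] = [
    ("backbone_32x", {"use_msa": False, "use_bleu": False, "factor": 32}),
    ("backbone_16x", {"use_msa": False, "use_bleu": False, "factor": 16}),
    ("backbone_16x_msa", {"use_msa": True, "use_bleu": False, "factor": 16}),
    ("backbone_16x_msa_bleu", {"use_msa": True, "use_bleu": True, "factor": 16}),
]

THRESHOLD_ABLATIONS: list[tuple[float, float, float]] = [
    (0.7, 0.2, 1.2),
    (0.65, 0.1, 1.3),
    (0.6, 0.1, 1.2),
]


def _model_for_row(base: ModelConfig, mode: str, entry) -> ModelConfig:
    cfg = ModelConfig.from_dict(base.to_dict())   # deep copy
    if mode == "modules":
        _, opts = entry
        cfg.use_msa = opts["use_msa"]
        cfg.use_bleu = opts["use_bleu"]
        cfg.encoder = replace(cfg.encoder, downsample_factor=opts["factor"])
    elif mode == "thresholds":
        a, b, g = entry
        cfg.bleu = replace(cfg.bleu, alpha=a, beta=b, gamma=g)
    else:
        raise ValueError(f"unknown ablation mode {mode!r}")
    return cfg


def ablation_suite(train_samples: list[LabeledSample],
                   val_samples: list[LabeledSample],
                   base_model: ModelConfig, base_train: TrainConfig,
                   mode: str = "modules",
                   seeds: tuple[int, ...] = (0,),
                   out_csv: str | Path | None = None) -> list[dict]:
    """Train/evaluate each ablation row (shared seeds) and tabulate metrics."""
    entries = MODULE_ABLATIONS if mode == "modules" else THRESHOLD_ABLATIONS
    rows = []
    for entry in entries:
        label = entry[0] if mode == "modules" else \
            "alpha_%.2f_beta_%.2f_gamma_%.2f" % entry
        per_seed = []
        cfg = None
        for seed in seeds:
            cfg = _model_for_row(base_model, mode, entry)
            cfg.seed = seed
            tcfg = replace(base_train, seed=seed)
            model = build_mbleformer(cfg)
            _, hist = train(model, train_samples, tcfg, val_data=val_samples)
            per_seed.append(hist.best_miou if hist.best_miou >= 0
                            else hist.records[-1].metrics.miou)
        rows.append({"label": label, "config": cfg.to_dict(),
                     "miou_per_seed": per_seed,
                     "miou_mean": float(np.mean(per_seed))})
    if out_csv is not None:
        lines = ["label,miou_mean," + ",".join(
            f"miou_seed{s}" for s in seeds)]
        for r in rows:
            lines.append(",".join(
                [r["label"], f"{r['miou_mean']:.4f}"]
                + [f"{v:.4f}" for v in r["miou_per_seed"]]))
        Path(out_csv).write_text("\n".join(lines) + "\n")
    return rows
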