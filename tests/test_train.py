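"""Training pipeline: augmentation, schedule, determinism, evaluation."""

import numpy as np
import pytest
from mbleformer import (EncoderConfig, ModelConfig,
                        SynthParams, TrainConfig, augment, build_mbleformer,
                        coarse_dropout, evaluate, generate_samples, hflip,
                        lr_at_epoch, rotate_sample, train, vflip)
from mbleformer.metrics import confusion_counts, metric_report
from mbleformer.train import _to_batch


@pytest.fixture(scope="module")
def tiny_samples():
    return generate_samples(8, SynthParams(size=(48, 48)), seed=77)


@pytest.fixture
def tiny_cfg():
    enc = EncoderConfig(embed_dim=8, depths=(1, 1, 1), num_heads=(1, 2, 4),
                        seed=3)
    return ModelConfig(encoder=enc, head_channels=4, seed=3)


# -- augmentation -----------------------------------------------------------


def test_augment_identity_when_probability_zero(tiny_samples, rng):
    cfg = TrainConfig(aug_prob=0.0)
    out = augment(tiny_samples[0], rng, cfg)
    assert np.array_equal(out.image, tiny_samples[0].image)
    assert np.array_equal(out.mask, tiny_samples[0].mask)


def test_flips_are_involutions(tiny_samples):
    s = tiny_samples[0]
    for f in (hflip, vflip):
        twice = f(f(s))
        assert np.array_equal(twice.image, s.image)
        assert np.array_equal(twice.mask, s.mask)


def test_flips_move_image_and_mask_together(tiny_samples):
    s = tiny_samples[0]
    out = hflip(s)
    assert np.array_equal(out.image, s.image[:, ::-1])
    assert np.array_equal(out.mask, s.mask[:, ::-1])


def test_rotation_keeps_mask_binary(tiny_samples):
    out = rotate_sample(tiny_samples[1], 17.3)
    assert set(np.unique(out.mask)).issubset({0, 1})
    assert out.image.shape == tiny_samples[1].image.shape


def test_coarse_dropout_leaves_mask_untouched(tiny_samples, rng):
    out = coarse_dropout(tiny_samples[2], rng)
    assert np.array_equal(out.mask, tiny_samples[2].mask)
    assert not np.array_equal(out.image, tiny_samples[2].image)


# -- learning-rate schedule -------------------------------------------------


@pytest.mark.parametrize("epoch,expected", [
    (0, 1e-4), (39, 1e-4), (40, 1e-5), (80, 1e-6), (120, 1e-7),
])
def test_lr_schedule_decimates_every_40_epochs(epoch, expected):
    assert lr_at_epoch(epoch, TrainConfig()) == pytest.approx(expected)


def test_history_lr_column_follows_schedule(tiny_samples, tiny_cfg):
    model = build_mbleformer(tiny_cfg)
    cfg = TrainConfig(epochs=3, batch_size=4, input_size=48, seed=0,
                      lr_decay_every=2)
    _, hist = train(model, tiny_samples[:6], cfg, val_data=tiny_samples[6:])
    assert [r.lr for r in hist.records] == [lr_at_epoch(e, cfg)
                                            for e in range(3)]


# -- training loop ----------------------------------------------------------


def test_training_is_deterministic(tiny_samples, tiny_cfg):
    losses = []
    for _ in range(2):
        model = build_mbleformer(tiny_cfg)
        cfg = TrainConfig(epochs=2, batch_size=4, input_size=48, seed=5)
        _, hist = train(model, tiny_samples[:6], cfg,
                        val_data=tiny_samples[6:])
        losses.append([r.loss for r in hist.records])
    assert losses[0] == losses[1]


def test_seed_isolation_between_init_and_data(tiny_samples, tiny_cfg):
    """Changing only the training seed must not change model init."""
    a = build_mbleformer(tiny_cfg)
    b = build_mbleformer(tiny_cfg)
    ca, cb = a.param_checksum(), b.param_checksum()
    train(a, tiny_samples[:4], TrainConfig(epochs=1, batch_size=4, seed=1))
    train(b, tiny_samples[:4], TrainConfig(epochs=1, batch_size=4, seed=2))
    assert ca == cb
    assert a.param_checksum() != b.param_checksum()   # different streams


def test_empty_training_split_rejected(tiny_cfg):
    model = build_mbleformer(tiny_cfg)
    with pytest.raises(ValueError):
        train(model, [], TrainConfig(epochs=1))


def test_overfit_single_batch():
    """The desk model memorises one batch of four synthetic 96x96 samples:
    at a constant learning rate the Dice+BCE loss falls below 0.1."""
    samples = generate_samples(4, SynthParams(size=(96, 96)), seed=55)
    model = build_mbleformer(ModelConfig(seed=0))
    cfg = TrainConfig(epochs=150, batch_size=4, input_size=96, seed=0,
                      aug_prob=0.0, lr_decay_every=1000)
    _, hist = train(model, samples, cfg)
    assert hist.records[-1].loss < 0.1
    assert hist.records[-1].loss < hist.records[0].loss * 0.25


# -- evaluation -------------------------------------------------------------


class _OracleModel:
    """Stub predictor that returns the ground truth (or a constant)."""

    def __init__(self, samples, constant=None):
        self.lookup = {s.image.tobytes(): s.mask for s in samples}
        self.constant = constant

    def predict_mask(self, x, threshold):
        imgs = (np.asarray(x).transpose(0, 2, 3, 1) * 255).round().astype(np.uint8)
        if self.constant is not None:
            return np.full(imgs.shape[:3], self.constant, dtype=np.uint8)
        return np.stack([self.lookup[i.tobytes()] for i in imgs])


def test_evaluate_ground_truth_scores_perfectly(tiny_samples):
    report = evaluate(_OracleModel(tiny_samples), tiny_samples)
    assert all(v == 1.0 for v in report.to_dict().values())


def test_evaluate_all_zero_predictor_has_zero_recall(tiny_samples):
    report = evaluate(_OracleModel(tiny_samples, constant=0), tiny_samples)
    assert report.recall == 0.0


def test_micro_counts_equal_sum_of_per_image_counts(tiny_samples, tiny_cfg):
    model = build_mbleformer(tiny_cfg).eval()
    total = None
    for s in tiny_samples:
        x, y = _to_batch([s])
        c = confusion_counts(model.predict_mask(x, 0.5),
                             y[:, 0].astype(np.uint8))
        total = c if total is None else total + c
    pooled = evaluate(model, tiny_samples, threshold=0.5)
    assert pooled.to_dict() == metric_report(total).to_dict()
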