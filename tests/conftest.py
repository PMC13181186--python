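import numpy as np
import pytest

from mbleformer import EncoderConfig, ModelConfig, SynthParams, generate_samples


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def desk_encoder() -> EncoderConfig:
    """The desk-scale backbone preset used throughout the CPU tests."""
    return EncoderConfig()


@pytest.fixture
def tiny_model_config() -> ModelConfig:
    """Smallest channel widths that still exercise every code path."""
    enc = EncoderConfig(embed_dim=8, depths=(1, 1, 1), num_heads=(1, 2, 4),
                        window_size=4, seed=7)
    return ModelConfig(encoder=enc, head_channels=4, seed=7)


@pytest.fixture(scope="session")
def synth_params_96() -> SynthParams:
    return SynthParams(size=(96, 96))


@pytest.fixture(scope="session")
def small_sample_set(synth_params_96):
    """Eight 96x96 synthetic image/mask pairs shared across tests."""
    return generate_samples(8, synth_params_96, seed=123)
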