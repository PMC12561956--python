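import numpy as np
import pytest

from litemrinet import ModelConfig, SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model_config():
    """A fast, fully structured configuration for training tests."""
    return ModelConfig(input_size=16, base_channels=8, shared_depth=2,
                       transformer_depths=(1, 1), attention_heads=2)


@pytest.fixture(scope="session")
def tiny_synth_config():
    return SyntheticConfig(image_size=16, tumor_area_range=(0.08, 0.2),
                           texture_scale=1.5, brain_axes_range=(0.3, 0.42))


@pytest.fixture(scope="session")
def tiny_dataset(tiny_synth_config):
    return [r["pair"] for r in generate_dataset(6, tiny_synth_config, seed=3)]
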