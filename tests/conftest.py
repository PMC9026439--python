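import numpy as np
import pytest

from dbnn.model import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_config(**overrides) -> ModelConfig:
    """Smallest architecture the four-pool layout allows: 16x16 input,
    a handful of channels; dropout off so eval == train geometry."""
    base = dict(depth=8, block_layout=[2, 2, 2, 2],
                channels_per_block=[2, 3, 3, 4], fc_width=6,
                image_size=16, dropout_rate=0.0)
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture
def tiny_cfg():
    return tiny_config()
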