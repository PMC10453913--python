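import numpy as np
import pytest

from gmtl.config import ModelConfig
from gmtl.data import Batch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Two tasks, short sequences — small enough for scalar oracles."""
    return ModelConfig(num_tasks=2, seq_len=5, feat_dim=3, encoder_hidden=4,
                       encoder_layers=1, num_layers=1, seed=7)


@pytest.fixture
def tiny_batch(rng, tiny_config):
    cfg = tiny_config
    x = rng.standard_normal((12, cfg.seq_len, cfg.feat_dim))
    y = [rng.integers(1, c + 1, 12) for c in cfg.task_classes]
    # make sure both classes occur in every task
    for yy in y:
        yy[0], yy[1] = 1, 2
    return Batch(x, y)
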