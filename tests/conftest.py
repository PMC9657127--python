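import numpy as np
import pytest

from crorelu.synthetic import SyntheticPatchConfig
from crorelu.training import synthetic_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def toy_dataset():
    """Shared desk-scale dataset: 300 patches/class at 64 px (threshold 16 px),
    split 80/20 into train/test. Generated once per session."""
    cfg = SyntheticPatchConfig(patch_size=64, seed=11)
    return synthetic_dataset(cfg, 300, split=0.8)
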