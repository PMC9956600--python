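import numpy as np
import pytest

from snagdet.backbone import SwinConfig
from snagdet.detector import ModelConfig, SnagDetector


@pytest.fixture(scope="session")
def tiny_swin_config() -> SwinConfig:
    return SwinConfig.tiny_test(seed=0)


@pytest.fixture(scope="session")
def tiny_model() -> SnagDetector:
    """One shared randomly initialised tiny-profile detector (read-only)."""
    return SnagDetector(ModelConfig.tiny_test(seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
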