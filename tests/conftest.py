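import numpy as np
import pytest

from neuroassay.config import AnalysisConfig


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
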