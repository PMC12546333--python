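import numpy as np
import pytest

from laamseg.model import ModelConfig, build_model


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_model():
    """Smallest usable segmentation model (96 px, quarter width)."""
    return build_model(ModelConfig(input_size=(96, 96), width_multiple=0.25, seed=0))
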