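import numpy as np
import pytest

from plaquescope import model as M


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model():
    """Small-width classifier at 64 px input (six pools -> 1x1) for fast
    inference-path tests; architecture identical in structure."""
    cfg = M.ModelConfig(input_px=64, conv_channels=(4, 4, 8, 8, 16, 16),
                        fc_sizes=(32, 16), seed=7)
    return M.build_model(cfg)


@pytest.fixture(scope="session")
def tiny_model_256():
    """Untrained 256 px-input classifier with small widths."""
    cfg = M.ModelConfig(conv_channels=(4, 4, 8, 8, 16, 16), fc_sizes=(64, 32), seed=3)
    return M.build_model(cfg)
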