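import numpy as np
import pytest

from cordseg import ModelConfig, PhantomConfig, build_scs_net, generate_phantom


@pytest.fixture(scope="session")
def small_config():
    """64x64 phantom config used throughout the cheap tests."""
    return PhantomConfig(image_size=64)


@pytest.fixture(scope="session")
def sample64(small_config):
    return generate_phantom(small_config, seed=11)


@pytest.fixture(scope="session")
def samples64(small_config):
    return [generate_phantom(small_config, seed=200 + i) for i in range(6)]


@pytest.fixture(scope="session")
def tiny_model():
    """Small untrained network (deterministic init) for contract tests."""
    return build_scs_net(ModelConfig(base_channels=8), seed=0)


class OracleStubModel:
    """Predicts exactly the reference mask it was given per image index."""

    def __init__(self, masks):
        self.masks = list(masks)
        self.calls = 0

    def predict_mask(self, image):
        mask = self.masks[self.calls % len(self.masks)]
        self.calls += 1
        return np.asarray(mask, dtype=np.uint8)


@pytest.fixture()
def oracle_stub_factory():
    return OracleStubModel
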