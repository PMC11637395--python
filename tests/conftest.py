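import numpy as np
import pytest

from eggpale import FlowConfig, FlowModel, PhantomSpec, generate_normal
from eggpale.flow.train import train_flow


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    return FlowConfig(image_size=8, n_levels=2, n_steps=2, hidden_width=8,
                      batch_size=4, n_epochs=1, seed=3)


@pytest.fixture
def identity_model():
    cfg = FlowConfig(image_size=4, n_levels=1, n_steps=2, hidden_width=8,
                     batch_size=2)
    return FlowModel(cfg, init="identity")


@pytest.fixture(scope="session")
def mini_trained():
    """A small flow trained briefly on 16x16 phantoms (shared across tests)."""
    cfg = FlowConfig(image_size=16, n_levels=2, n_steps=2, hidden_width=16,
                     batch_size=16, n_epochs=2, seed=11)
    records = generate_normal(PhantomSpec(size=16, seed=11), 64)
    model = FlowModel(cfg, init="random")
    train_flow(model, [r.image for r in records], cfg)
    return model
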