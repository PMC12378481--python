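import numpy as np
import pytest

from dam.encoders import ModelConfig
from dam.fusion import DAMNet, FusionConfig
from dam.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six patients, 16-px crops: structural fixture for I/O and shapes."""
    return generate_cohort(SynthConfig(n_patients=6, image_size=16, seed=3))


@pytest.fixture(scope="session")
def small_cohort():
    """Twenty patients, 32-px crops, strong dynamics signal."""
    return generate_cohort(SynthConfig(n_patients=20, image_size=32,
                                       effect_size=2.0, seed=7))


@pytest.fixture(scope="session")
def model_cfg():
    return ModelConfig(embed_dim=32, n_heads=4, cnn_width=4,
                       marker_hidden=16, seed=0)


@pytest.fixture()
def tim_net(model_cfg, tiny_cohort):
    net = DAMNet(model_cfg, FusionConfig(mode="tim"))
    net.marker_encoder.scaler.fit(
        [o.panel for p in tiny_cohort for o in p.marker_series])
    return net


def seeded_rng(seed=0):
    return np.random.default_rng(seed)
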