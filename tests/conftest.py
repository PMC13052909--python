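import numpy as np
import pytest

import fedstroke as fs


@pytest.fixture(scope="session")
def small_multimodal():
    """120-pair separable multimodal dataset, 16x16 images."""
    return fs.generate_multimodal(
        120, stroke_fraction=0.4, missing_rate=0.05, height=16, width=16, seed=11
    )


@pytest.fixture(scope="session")
def tiny_model():
    """4-hidden-unit network over 3 static features and 4-wide rows."""
    return fs.init_model(static_dim=3, seq_input=4, mlp_hidden=(4,), gru_hidden=4, seed=7)


@pytest.fixture
def tiny_batch():
    rng = np.random.default_rng(5)
    xs = rng.normal(size=(3, 3))
    xq = rng.normal(size=(3, 3, 4))  # 3 timesteps
    y = np.array([0.0, 1.0, 1.0])
    return xs, xq, y


@pytest.fixture
def smoke_config():
    cfg = fs.ExperimentConfig()
    cfg.seed = 11
    cfg.data.n_samples = 120
    cfg.data.image_height = cfg.data.image_width = 16
    cfg.federated.rounds = 2
    cfg.federated.epochs_per_client = 2
    return cfg
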