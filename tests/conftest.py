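import numpy as np
import pytest

import hopfbif as hb
from hopfbif.regression import TrainingConfig, train_regressor


@pytest.fixture(scope="session")
def connectome10():
    """A fixed random 10-region connectome shared across the suite."""
    return hb.random_connectome(10, seed=0)


@pytest.fixture(scope="session")
def training_set_small(connectome10):
    """A small synthetic training set for fast unit-level checks."""
    return hb.generate_training_set(200, 50, connectome10, 1.0, hb.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def trained_seq_model(connectome10):
    """The desk-scale sequence regressor: N=10, S=2000, W=50, tiny preset.

    Trained once per session and reused by recovery, inference and
    end-to-end tests.
    """
    data = hb.generate_training_set(2000, 50, connectome10, 1.0, hb.SimulationConfig(seed=7))
    model = train_regressor(
        data, TrainingConfig(approach="sequence", model_scale="tiny", epochs=12, seed=3)
    )
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
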