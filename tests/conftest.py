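import numpy as np
import pytest

from pathae.conv_autoencoder import StageConfig, TrainConfig, init_stage, train_stage
from pathae.reduction_network import default_class_specs
from pathae.synthetic_data import generate_dataset, make_motif_bank


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def bank():
    return make_motif_bank(8, 4, seed=1)


@pytest.fixture(scope="session")
def specs():
    return default_class_specs()


@pytest.fixture(scope="session")
def small_dataset(specs):
    """Three placement classes, 10 images each, 32 px — quick unit-test food."""
    return generate_dataset(specs, n_per_class=10, size=32, seed=101)


@pytest.fixture(scope="session")
def tiny_stage():
    """Small seeded stage (3x3 filters, 2 filters, RGB input), untrained."""
    return init_stage(3, 2, 3, seed=7)


@pytest.fixture(scope="session")
def trained_small_stage(small_dataset):
    """One briefly trained stage shared by tests that need real filters."""
    stage, history = train_stage(
        small_dataset.train[0],
        StageConfig(5, 8),
        TrainConfig(learning_rate=3e-3, batch_size=8, steps=60, lambda_s=1e-3, seed=11),
    )
    return stage, history
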