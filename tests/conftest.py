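import numpy as np
import pytest

from eegfatigue.entropy import build_feature_table
from eegfatigue.preprocess import preprocess_pipeline
from eegfatigue.synthetic import default_params, generate_cohort

TEST_FS = 200.0


@pytest.fixture(scope="session")
def moderate_params():
    """Moderate-effect model at the reduced test sampling rate."""
    return default_params("moderate", fs=TEST_FS, duration_s=10.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(moderate_params):
    """4 subjects x 2 states x 10 s."""
    return generate_cohort(4, moderate_params)


@pytest.fixture(scope="session")
def small_epochs(small_cohort):
    epochs = []
    for rec in small_cohort:
        kept, _ = preprocess_pipeline(rec)
        epochs.extend(kept)
    return epochs


@pytest.fixture(scope="session")
def feature_table(small_epochs):
    """80 epochs x (22 entropy + 8 RBP) features."""
    return build_feature_table(small_epochs, include_rbp=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
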