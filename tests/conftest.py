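import warnings

import numpy as np
import pytest

from hybridbci import Modality, default_montage, preprocess_dataset
from hybridbci.simulate import GeneratorConfig, simulate_subject


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def small_dataset():
    """8 short trials (4.8 s) — fast, used wherever trial counts are small."""
    cfg = GeneratorConfig(
        n_sessions=1, trials_per_session=8, trial_duration_s=4.8, seed=11
    )
    return simulate_subject(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """One full protocol-sized subject (6 x 20 trials of 24 s)."""
    return simulate_subject(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def preprocessed_dataset(default_dataset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return preprocess_dataset(default_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
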