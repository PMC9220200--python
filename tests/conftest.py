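import numpy as np
import pytest

from mhclstm.substitution import load_substitution_matrix
from mhclstm.synthetic import (
    MotifSpec,
    SyntheticDatasetConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def blosum62():
    return load_substitution_matrix("BLOSUM62")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def strong_motif_records():
    """A small class-I-style dataset with a strong planted motif."""
    config = SyntheticDatasetConfig(n_peptides=300, seed=7)
    return generate_dataset(config, MotifSpec(strength=3.0))


@pytest.fixture(scope="session")
def quick_trained_model(strong_motif_records):
    """A briefly trained model for tests that need any non-trivial model."""
    from mhclstm.trainer import TrainingConfig, train_model

    config = TrainingConfig(epochs=3, seed=11)
    return train_model(strong_motif_records, config)
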