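import numpy as np
import pytest

from nemafauna.annotations import default_annotations, default_guild_weights
from nemafauna.design import build_dominance_roster
from nemafauna.metrics import indices_table
from nemafauna.synthgen import generate_dataset


@pytest.fixture(scope="session")
def aset():
    return default_annotations()


@pytest.fixture(scope="session")
def weights():
    return default_guild_weights()


@pytest.fixture(scope="session")
def roster():
    return build_dominance_roster()


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic study (93 plots), shared across tests."""
    return generate_dataset(seed=7)


@pytest.fixture(scope="session")
def indices(dataset, aset, weights):
    return indices_table(
        dataset.counts_frame, dataset.samples_frame, aset, weights, dataset.covariates
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
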