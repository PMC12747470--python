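import pytest

from mofscreen.synth import (
    DEFAULT_FORCE_FIELD,
    SyntheticToxicitySpec,
    make_guest_models,
    make_toxicity_dataset,
)
from mofscreen.toxicity import load_metal_table, train_toxicity_classifier


@pytest.fixture(scope="session")
def guests():
    return make_guest_models()


@pytest.fixture(scope="session")
def ff():
    return DEFAULT_FORCE_FIELD


@pytest.fixture(scope="session")
def metal_table():
    return load_metal_table()


@pytest.fixture(scope="session")
def small_dataset():
    """Small toxicity benchmark shared across tests (featurization is cached)."""
    return make_toxicity_dataset(SyntheticToxicitySpec(n=600, seed=11))


@pytest.fixture(scope="session")
def trained_classifier(small_dataset):
    clf, report = train_toxicity_classifier(small_dataset, seed=11)
    return clf, report
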