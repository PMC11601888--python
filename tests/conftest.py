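import pytest

from funlnc.classifier import LabeledSet
from funlnc.features import build_feature_matrix
from funlnc.pipeline import network_from_bundle
from funlnc.synthetic import SimConfig, simulate_dataset, worked_micro_example


@pytest.fixture(scope="session")
def micro_bundle():
    return worked_micro_example()


@pytest.fixture(scope="session")
def micro_network(micro_bundle):
    return network_from_bundle(micro_bundle)


@pytest.fixture(scope="session")
def micro_matrix(micro_network):
    return build_feature_matrix(micro_network)


@pytest.fixture(scope="session")
def small_bundle():
    """60 lncRNAs, informative defaults; shared by the model-level tests."""
    return simulate_dataset(SimConfig(n_lncrnas=60, seed=7))


@pytest.fixture(scope="session")
def small_network(small_bundle):
    return network_from_bundle(small_bundle)


@pytest.fixture(scope="session")
def small_matrix(small_network):
    return build_feature_matrix(small_network)


@pytest.fixture(scope="session")
def small_labeled(small_bundle):
    pos = tuple(i for i, z in small_bundle.labels.items() if z == 1)
    neg = tuple(i for i, z in small_bundle.labels.items() if z == 0)
    return LabeledSet(pos, neg)
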