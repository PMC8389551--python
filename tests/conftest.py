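import numpy as np
import pytest

from spikelat.mnsd import MNSD
from spikelat.neuron import NeuronParams


@pytest.fixture(scope="session")
def default_params() -> NeuronParams:
    return NeuronParams()


@pytest.fixture(scope="session")
def trained_mnsd() -> MNSD:
    """One fully trained 4-branch sequence detector, shared across tests."""
    model = MNSD()
    model._fit_result = model.fit(n_trials=300)
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
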