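import numpy as np
import pytest

from dorna import classify
from dorna.references import DEFAULT_ADAPTER3, synthetic_precursor


@pytest.fixture(scope="session")
def human_refs():
    return synthetic_precursor("human")


@pytest.fixture(scope="session")
def human_anchor(human_refs):
    return classify.derive_anchor(human_refs, next(iter(human_refs.records)))


@pytest.fixture(scope="session")
def fly_refs():
    return synthetic_precursor("fly")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def adapter():
    return DEFAULT_ADAPTER3
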