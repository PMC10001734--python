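import numpy as np
import pytest
from hypothesis import settings

from ifmcdm import load_fixture

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def expert_panel():
    return load_fixture("expert_panel")


@pytest.fixture(scope="session")
def equipment_judgments():
    return load_fixture("equipment_aggregated_judgments")


@pytest.fixture(scope="session")
def human_talent_Z():
    elements, Z = load_fixture("human_talent_direct_relation")
    return elements, np.asarray(Z)


@pytest.fixture(scope="session")
def decision_matrix():
    return load_fixture("decision_matrix")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
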