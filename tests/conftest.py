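import numpy as np
import pytest

from microguild.data_model import AbundanceTable
from microguild.simulate import SimConfig, generate_study


@pytest.fixture()
def tiny_counts() -> AbundanceTable:
    return AbundanceTable(
        ["s1", "s2"], ["otuA", "otuB"], np.array([[5.0, 5.0], [1.0, 3.0]]), "counts"
    )


@pytest.fixture(scope="session")
def small_study():
    """One deterministic synthetic study reused across tests."""
    return generate_study(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=42)
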