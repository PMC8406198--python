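import numpy as np
import pytest

from cycscreen import synthetic
from cycscreen.screen import ProteinRecord


@pytest.fixture(scope="session")
def family_records():
    """A default-configuration cluster family (20 members, seed 5)."""
    records, truth = synthetic.gen_cluster_family(synthetic.FamilyConfig(seed=5))
    return records, truth


@pytest.fixture(scope="session")
def small_family():
    records, truth = synthetic.gen_cluster_family(
        synthetic.FamilyConfig(n_members=8, seed=7)
    )
    return records, truth


@pytest.fixture(scope="session")
def noiseless_titration():
    return synthetic.gen_titration(synthetic.TitrationConfig(noise_sd=0.0, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(seq: str, rid: str = "r1") -> ProteinRecord:
    return ProteinRecord(id=rid, seq=seq)
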