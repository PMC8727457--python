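import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eegmfcc import fixtures
from eegmfcc.qm import MockEngine

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_complex():
    """5-mer chain plus chromophore; contacts at 3.5 (residue 2) and 6.0
    (residue 4) angstrom."""
    return fixtures.make_toy_complex(
        n_residues=5, contact_distances={2: 3.5, 4: 6.0}, seed=1
    )


@pytest.fixture(scope="session")
def standard_toy():
    """8-mer benchmark complex; returns (system, charge model, chromophore)."""
    return fixtures.standard_toy(seed=1)


@pytest.fixture(scope="session")
def pairwise_engine():
    return MockEngine(fixtures.preset_pairwise(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
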