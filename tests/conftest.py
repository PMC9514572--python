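import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from graftnp import ForceField, SimSettings, sample_free_chains

hypothesis_settings.register_profile("repro", derandomize=True,
                                     deadline=None)
hypothesis_settings.load_profile("repro")


@pytest.fixture(scope="session")
def ff():
    return ForceField()


@pytest.fixture(scope="session")
def free_chain_ensembles_small(ff):
    """Short free-chain runs shared by the analysis sanity tests."""
    settings = SimSettings(n_steps=120_000, n_samples=60, seed=42)
    return sample_free_chains([5, 10, 18], ff, settings, n_chains=12)


@pytest.fixture(scope="session")
def free_chain_ensembles(ff):
    """Production-grade free-chain ensembles for the stiffness and scaling
    measurements (L = 5, 10, 18, 40 bases)."""
    settings = SimSettings(n_steps=400_000, n_samples=100, seed=2024)
    return sample_free_chains([5, 10, 18, 40], ff, settings, n_chains=16)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (keeps tests order-independent)."""
    return np.random.default_rng(7)
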