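import numpy as np
import pytest

from metgp import McmcSettings, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """100 accessions + 2 checks, 3 sites: the standard small fixture."""
    cfg = SimConfig(n_lines=100, n_markers=300, n_sites=3, n_checks=2, seed=9)
    bundle, truth = simulate_dataset(cfg)
    return bundle, truth


@pytest.fixture()
def fast_mcmc():
    return McmcSettings(n_iterations=1000, burn_in=300, thinning=2, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
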