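import numpy as np
import pytest

from grncf import RunConfig, SimSpec, gpalm_fit, simulate


@pytest.fixture(scope="session")
def small_bundle():
    """Default-condition planted bundle (60 genes, 10 TFs, 30 samples)."""
    return simulate(SimSpec(seed=11))


@pytest.fixture(scope="session")
def small_fit(small_bundle):
    """One joint fit on the small bundle, shared across tests."""
    return gpalm_fit(small_bundle.expression, small_bundle.priors, RunConfig(seed=11, max_iter=300))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
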