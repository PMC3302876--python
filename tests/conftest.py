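import numpy as np
import pytest

from spip import fixtures, pipeline


@pytest.fixture(scope="session")
def default_bundle():
    """One default-preset benchmark bundle, shared across tests."""
    return fixtures.generate(seed=11)


@pytest.fixture(scope="session")
def default_run(default_bundle):
    """Full platform run on the shared bundle."""
    return pipeline.run_spip(default_bundle, seed=11)


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale-within-desk-scale parameters for fast IO/CLI tests."""
    return fixtures.FixtureParams(
        n=80,
        m=14,
        seed_size=8,
        holdout_size=4,
        n_neg_labels=24,
        n_module_known=8,
        n_background_known=10,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
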