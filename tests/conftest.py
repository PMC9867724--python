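import numpy as np
import pytest

from scanmil import PhantomConfig, generate_phantoms


@pytest.fixture(scope="session")
def small_cohort():
    """A small phantom cohort shared across tests (20 scans, strong signal)."""
    cfg = PhantomConfig(n_scans=20, slices_per_scan=(8, 16), seed=42)
    return cfg, generate_phantoms(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
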