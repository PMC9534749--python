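import numpy as np
import pytest

from saccadeflow import SimConfig, synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_session():
    """A compact head-fixed session shared by read-only tests."""
    cfg = SimConfig(session_length_s=400.0, n_units=24, seed=7)
    return synthetic.generate_session(
        cfg, conditions=("grey_screen", "pseudo", "grating")
    )
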