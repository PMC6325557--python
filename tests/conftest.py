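import numpy as np
import pytest

from cbgt.protocol import run_covert_learning_protocol


@pytest.fixture(scope="session")
def protocol_result():
    """One full covert-learning experiment (12 sessions x C0/C1/C2), shared
    across the protocol-level and acceptance tests."""
    return run_covert_learning_protocol(n_sessions=12, master_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
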