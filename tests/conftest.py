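import numpy as np
import pytest

import morphograft as mg


@pytest.fixture(scope="session")
def params():
    """Equilibrium-completed default parameter set."""
    return mg.default_parameters()


@pytest.fixture(scope="session")
def coarse_mesh():
    return mg.build_mesh(half_width=10.0, target_edge=2.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
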