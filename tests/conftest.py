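import numpy as np
import pytest

import bmrdkit as bk


@pytest.fixture(scope="session")
def ref_system():
    """NH2-like three-spin reference cluster with +-700 Hz proton shifts."""
    return bk.three_spin_reference_system()


@pytest.fixture(scope="session")
def proton_relax():
    """30 s^-1 random-field relaxation on both protons."""
    return bk.RelaxationSpec({"H1": 30.0, "H2": 30.0})


@pytest.fixture(scope="session")
def small_powder():
    return bk.repulsion_scheme(20)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
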