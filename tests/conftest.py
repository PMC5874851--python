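import numpy as np
import pytest

import rsbeam as rb


@pytest.fixture(scope="session")
def lexan():
    return rb.get_material("lexan")


@pytest.fixture(scope="session")
def water():
    return rb.get_material("water")


@pytest.fixture(scope="session")
def rs_reference():
    """The study slab at the commissioning position (6.5 cm Lexan, face at 36.5 cm)."""
    return rb.default_range_shifter()


@pytest.fixture(scope="session")
def truth():
    """Truth open-beam phase spaces for the five study energies."""
    return rb.default_truth()


@pytest.fixture(scope="session")
def commissioning_fe(truth, rs_reference):
    """Noise-free commissioning dataset generated from Fermi-Eyges physics."""
    return rb.make_lynx_dataset(truth, rs_reference, noise_sd_mm=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20160308)
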