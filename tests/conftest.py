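import numpy as np
import pytest

from specseg.design import AcquisitionDesign, build_spt


@pytest.fixture(scope="session")
def design():
    """Strictly periodic reference design (34 s off everywhere)."""
    return AcquisitionDesign()


@pytest.fixture(scope="session")
def jittered_design():
    return AcquisitionDesign.jittered(7)


@pytest.fixture(scope="session")
def spt(jittered_design):
    return build_spt(jittered_design)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
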