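import numpy as np
import pytest

from swarmsim.core import SwarmParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def params():
    """A generic parameter set with all three zones populated."""
    return SwarmParams(
        gamma=1.0, scale=2.0, gain=1.0,
        chi_rep=2.0, r_rep=1.0,
        chi_ali=1.5, r_ali=2.5,
        chi_att=3.0, r_att=4.0,
        chi_res=2.0, r_res=5.0,
    )
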