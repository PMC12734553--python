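import math

import numpy as np
import pytest

from flipkin import TwoCompartmentParams
from flipkin.examples import example2_params


@pytest.fixture(scope="session")
def small_params():
    """Small grid matching the schematic carrier (mE=8, mI=5), M/N = 3."""
    return TwoCompartmentParams(mE=8, mI=5, KEI=1.0, KIE=1.0, N=100, M=300)


@pytest.fixture(scope="session")
def ex2_params():
    """Continuum configuration: KEI = 1/(3 tau), KIE = 2/(3 tau), M/N = 100."""
    return example2_params(M_over_N=100.0, N=100, tau=1.0)


@pytest.fixture(scope="session")
def balanced_params():
    """Finite grid with KEI*mE == KIE*mI (first-moment ODEs close exactly)."""
    return TwoCompartmentParams(mE=50, mI=25, KEI=1.0, KIE=2.0, N=100, M=1500)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


LN2 = math.log(2.0)
LN4 = math.log(4.0)
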