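import numpy as np
import pytest

from fuse_kinetics.leaflets import LipidSpec, MembraneSpec

#: Reference parameters of the conical-lipid partition example:
#: kappa = 20 kBT, a = 0.65 nm^2, c0 = -0.4 nm^-1, R = 40 nm.
DOPE = LipidSpec(c0=-0.4, a=0.65, name="DOPE")


@pytest.fixture
def dope():
    return DOPE


@pytest.fixture
def membrane():
    def make(f: float) -> MembraneSpec:
        return MembraneSpec(kappa=20.0, R=40.0, f=f)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20210763)
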