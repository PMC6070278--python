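import numpy as np
import pytest

from protoflux.metabolism import FluxFunction, get_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def keystone_recycler_net():
    return get_fixture("keystone_recycler")


@pytest.fixture
def far_flux():
    return FluxFunction(get_fixture("keystone_recycler_far"))


# hand-transcribed closed-form fluxes used as independent oracles
def phi_keystone_recycler(a, b, kcat_a=1.0, kcat_b=1.0, cw_a=1.0, cm_b=2.0):
    return kcat_a * a + cm_b * min(cw_a * kcat_a * a, kcat_b * b)


def phi_serial3(a, b, c, cm_b=4.0, cm_g=4.0):
    return a + cm_b * min(a, b) + cm_g * min(a, b, c)


def phi_parallel3(a, b, c, cm_b=4.0, cm_g=4.0):
    return a + cm_b * min(a, b) + cm_g * min(a, c)


def phi_bimolecular3(a, b, c, cm_a=2.5, cm_b=2.5, cm_g=4.0):
    return cm_a * a + cm_b * b + cm_g * min(a, b, c)
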