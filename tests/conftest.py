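import numpy as np
import pytest

from mp2rageme import build_lookup, load_protocol


@pytest.fixture(scope="session")
def me_protocol():
    """The multi-echo (MP2RAGEME) protocol: TR 6.72 s, TI 670/3855 ms."""
    return load_protocol("mp2rageme")


@pytest.fixture(scope="session")
def mp_protocol():
    """The single-echo reference (MP2RAGE) protocol: TR 6 s, TI 1000/3200 ms."""
    return load_protocol("mp2rage")


@pytest.fixture(scope="session")
def megre_protocol():
    return load_protocol("megre")


@pytest.fixture(scope="session")
def me_lut(me_protocol):
    return build_lookup(me_protocol)


@pytest.fixture(scope="session")
def mp_lut(mp_protocol):
    return build_lookup(mp_protocol)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
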