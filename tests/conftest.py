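import pytest

from anklewalker import NumericsConfig, WalkerParams, make_fixtures


@pytest.fixture(scope="session")
def params() -> WalkerParams:
    """Standard parameter set (adult-human morphology, calibrated spring)."""
    return WalkerParams()


@pytest.fixture(scope="session")
def numerics() -> NumericsConfig:
    return NumericsConfig()


@pytest.fixture(scope="session")
def oracle(params):
    """Canonical constants recomputed by independent brute-force oracles
    (circle intersection, bisection, quadrature, simulation)."""
    return make_fixtures(params)
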