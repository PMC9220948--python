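import pytest

from raftsize import BilayerParams, ElectrostaticProfile


@pytest.fixture(scope="session")
def default_params() -> BilayerParams:
    return BilayerParams()


@pytest.fixture(scope="session")
def default_profile(default_params) -> ElectrostaticProfile:
    """Shared electrostatic profile for the default parameters.

    Building it tabulates ~400 adaptive quadratures, so the session reuses
    one instance wherever the defaults are involved.
    """
    return ElectrostaticProfile(default_params)
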