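import pytest

import inbpower as ip


@pytest.fixture(scope="session")
def fixtures():
    return ip.load_cctg_fixtures()


@pytest.fixture(scope="session")
def co17(fixtures):
    """CO.17 (all patients) pooled parameters with illustrative increments."""
    return fixtures["CO.17 (all patients)"].to_params(delta_e=0.1, delta_c=3000)


@pytest.fixture(scope="session")
def one_sided():
    return ip.TestSpec(alpha=0.05, target_power=0.80, wtp=100_000.0)
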