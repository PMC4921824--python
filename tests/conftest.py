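import numpy as np
import pytest

from oligoeq import (
    MixedSystemParams,
    SelfSystemParams,
    ThermoContext,
)

NM = 1e-9


@pytest.fixture(scope="session")
def ctx() -> ThermoContext:
    return ThermoContext()


@pytest.fixture(scope="session")
def self_A() -> SelfSystemParams:
    """Aβ40: fitted oligomer free energy and fibril CAC."""
    return SelfSystemParams(label="self_A", dG_oligo=-36.3, cac_fib=222 * NM)


@pytest.fixture(scope="session")
def self_B() -> SelfSystemParams:
    """Aβ42: fitted oligomer free energy and fibril CAC."""
    return SelfSystemParams(label="self_B", dG_oligo=-36.3, cac_fib=86 * NM)


@pytest.fixture(scope="session")
def mixed_params() -> MixedSystemParams:
    """Fitted two-species bond free energies (kJ/mol)."""
    return MixedSystemParams(dG_AA=-36.3, dG_BB=-36.3, dG_AB=-32.6)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160627)
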