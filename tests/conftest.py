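import numpy as np
import pytest

from luxkin import RateConstants, InitialConditions


@pytest.fixture(scope="session")
def true_rates() -> RateConstants:
    """Fixture ground-truth rates (K_M^F = 1.5 uM, K_M^a = 30 uM)."""
    from luxkin.synthetic import DEFAULT_TRUE_RATES

    return DEFAULT_TRUE_RATES


@pytest.fixture(scope="session")
def t15() -> np.ndarray:
    """The acquisition grid of the single-turnover assay: 15 s, 1000 points."""
    return np.linspace(0.0, 15.0, 1000)


@pytest.fixture(scope="session")
def default_ic() -> InitialConditions:
    return InitialConditions(L0=1e-6, F0=15e-6, A0=50e-6)
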