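import numpy as np
import pytest

from matesense.core_model import (
    CommunicationParams,
    DoseResponseCurve,
    PopulationComposition,
)


@pytest.fixture
def unit_params():
    """All rates 1: the dimensionless reference parameterization."""
    return CommunicationParams(
        alpha_secretion_rate=1.0,
        bar1_secretion_rate=1.0,
        bar1_specific_activity=1.0,
    )


@pytest.fixture
def bar1delta_params():
    """No Bar1 secretion: the protease-null communication regime."""
    return CommunicationParams(
        alpha_secretion_rate=1.0,
        bar1_secretion_rate=0.0,
        bar1_specific_activity=1.0,
    )


@pytest.fixture
def hill_curve():
    return DoseResponseCurve(r_max=1000.0, ec50=1.0, hill_n=1.0, baseline=0.0)


@pytest.fixture
def balanced_comp():
    return PopulationComposition(rho_a=1.0, rho_alpha=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
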