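import numpy as np
import pytest

from probioferm import fixtures as fx
from probioferm.screening import FactorSpec, build_pb_design


@pytest.fixture(scope="session")
def biomass_design():
    """The 37-run / 14-factor screening design (36 base + 1 center)."""
    return build_pb_design(fx.BIOMASS_FACTORS, 36, 1, seed=7)


@pytest.fixture(scope="session")
def eps_design():
    """The 13-run / 5-factor screening design (12 base + 1 center)."""
    return build_pb_design(fx.EPS_FACTORS, 12, 1, seed=7)


@pytest.fixture
def small_factors():
    return [
        FactorSpec("alpha", "A", 0, 5, 10),
        FactorSpec("beta", "B", 0, 1, 2),
        FactorSpec("gamma", "C", 0, 0.5, 1),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
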