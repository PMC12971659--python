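import numpy as np
import pytest

from oshprior import (
    CASE_STUDY_FUSED_WEIGHTS,
    labor_protection_problem,
    run_rankers,
)


@pytest.fixture(scope="session")
def problem():
    """The bundled 5×6 labor-protection decision problem."""
    return labor_protection_problem()


@pytest.fixture(scope="session")
def fused_weights():
    """The case study's published fused weight vector."""
    return CASE_STUDY_FUSED_WEIGHTS


@pytest.fixture(scope="session")
def method_rankings(problem, fused_weights):
    """All six method rankings computed with the fused weights."""
    return run_rankers(problem, fused_weights)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
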