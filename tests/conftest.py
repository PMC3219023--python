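import numpy as np
import pytest

from septiclass import (
    EffectModel,
    PanelSpec,
    generate_cohort_design,
    simulate_expression,
)


@pytest.fixture(scope="session")
def panel():
    return PanelSpec.default()


@pytest.fixture(scope="session")
def design():
    return generate_cohort_design(20, 38, 27)


@pytest.fixture(scope="session")
def study_matrix(design, panel):
    """Default-condition expression matrix: 85 samples × 42 markers."""
    return simulate_expression(design, panel, EffectModel.default(panel), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
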