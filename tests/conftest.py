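import pytest

from gebvrel import PopulationParams


@pytest.fixture
def example1_params() -> PopulationParams:
    """First worked example: one of two equal subpopulations."""
    return PopulationParams(n_reference=1000, heritability=0.3, q2=0.8, m_effective=400)


@pytest.fixture
def example2_params() -> PopulationParams:
    """Second worked example: single reference population."""
    return PopulationParams(n_reference=5000, heritability=0.3, q2=0.8, m_effective=400)
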