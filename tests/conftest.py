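import numpy as np
import pytest

from phagerm.config import default_parameters


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_params():
    """Desk-scale parameters: small population, short horizon."""
    return default_parameters(
        initial_population=50,
        supply_per_step=25,
        steps=10,
        burst_size=5,
    )


@pytest.fixture
def fig3_params():
    """Test-lineage preset: 1000 background + 10 marked-B phage, equal p_B."""
    return default_parameters(
        test_lineage_size=10,
        test_lineage_p_B=0.5,
        test_lineage_pattern="B",
        record_events=False,
    )
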