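import numpy as np
import pytest

from ecoturnover import AbundanceMatrix, SyntheticConfig, generate_assemblage


@pytest.fixture
def small_matrix() -> AbundanceMatrix:
    """4 species x 5 years, mixed common/rare, one flickering absence."""
    values = np.array(
        [
            [50.0, 40, 60, 55, 45],
            [10.0, 12, 8, 11, 9],
            [3.0, 0, 4, 0, 2],
            [0.0, 1, 0, 0, 1],
        ]
    )
    return AbundanceMatrix(["sprat", "whiting", "goby", "eel"], range(1981, 1986), values)


@pytest.fixture(scope="session")
def default_synthetic():
    """One default synthetic assemblage shared across tests (seed fixed)."""
    return generate_assemblage(SyntheticConfig(seed=20260901))
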