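import numpy as np
import pytest

from regpes import lj_decomposition, weighted_decomposition


@pytest.fixture
def lj_dataset():
    """Lennard-Jones 12-6 decomposition spanning the well (minimum at r=2^(1/6))."""
    return lj_decomposition(1.0, 1.0, np.linspace(0.9, 2.5, 40))


@pytest.fixture
def weighted_exact():
    """Noise-free two-term decomposition with weights (0.7, 0.3)."""
    return weighted_decomposition([0.7, 0.3])


@pytest.fixture
def double_well_dataset():
    """Exact three-term decomposition of a double-well profile (three segments)."""
    return weighted_decomposition(
        [0.5, 0.3, 0.2],
        grid=np.linspace(0.25, 0.85, 41),
        curve="double_well",
        curve_params={"minima": (0.25, 0.75)},
    )
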