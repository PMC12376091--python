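import numpy as np
import pytest

from ionpair.hnc import RadialGrid
from ionpair.model import Species, build_model


@pytest.fixture(scope="session")
def restricted_22():
    """Restricted 2:2 primitive model: both diameters 4.6 A, water at 25 C."""
    return build_model(
        [Species("M", 2.0, 4.6), Species("X", -2.0, 4.6)], 78.36, 298.15
    )


@pytest.fixture(scope="session")
def salt_11():
    """1:1 primitive model, diameters 4.6 A."""
    return build_model(
        [Species("M", 1.0, 4.6), Species("X", -1.0, 4.6)], 78.36, 298.15
    )


@pytest.fixture(scope="session")
def sulfate_template():
    """2:2 template with fixed anion diameter 4.6 A; cation diameter is the
    quantity the fit varies (placeholder 3.0 A)."""
    return build_model(
        [Species("M", 2.0, 3.0), Species("X", -2.0, 4.6)], 78.36, 298.15
    )


@pytest.fixture(scope="session")
def fast_grid():
    """Smallest permitted radial grid; used where speed matters more than
    far-field tail resolution."""
    return RadialGrid(2**12, 0.02)


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(1234))
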