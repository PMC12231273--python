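import numpy as np
import pytest

from paranmr import lebedev_grid, reference_grid, synthetic_system


@pytest.fixture(scope="session")
def ni_like():
    """Synthetic S=1 anisotropic system (Ni(II)-like regime) with protons."""
    return synthetic_system(3, S=1.0)


@pytest.fixture(scope="session")
def grid26():
    return lebedev_grid(26)


@pytest.fixture(scope="session")
def ref_grid():
    return reference_grid()


@pytest.fixture(scope="session")
def rotations():
    """Five seeded random proper rotations."""
    rng = np.random.default_rng(42)
    from paranmr.synth import random_rotation
    return [random_rotation(rng) for _ in range(5)]
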