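import numpy as np
import pytest

from turnext.fixtures import build_backbone
from turnext.turns import load_definitions, load_regions


@pytest.fixture(scope="session")
def definitions():
    return load_definitions()


@pytest.fixture(scope="session")
def regions():
    return load_regions()


@pytest.fixture
def ideal_helix_chain():
    """20-residue chain at alpha-helix core dihedrals."""
    n = 20
    return build_backbone([(-63.0, -40.0, 180.0)] * n, ["ALA"] * n)


@pytest.fixture
def ideal_strand_chain():
    """20-residue chain at beta-strand core dihedrals."""
    n = 20
    return build_backbone([(-120.0, 135.0, 180.0)] * n, ["VAL"] * n)


def random_angle_spec(rng: np.random.Generator, n: int):
    """Per-residue (phi, psi, omega) drawn uniformly on the circle."""
    return [tuple(rng.uniform(-179.99, 180.0, 3)) for _ in range(n)]
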