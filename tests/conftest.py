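import numpy as np
import pytest

from iontrack import build_default_baseline
from iontrack.genome import build_nucleus_model
from iontrack.geometry import NucleusGeometry


@pytest.fixture(scope="session")
def baseline():
    return build_default_baseline()


@pytest.fixture(scope="session")
def geometry():
    return NucleusGeometry()


@pytest.fixture(scope="session")
def small_model(geometry):
    """Reduced chromatin model (100 Mbp) for damage-rule tests."""
    return build_nucleus_model(geometry, genome_length=1.0e8, seed=11)


@pytest.fixture(scope="session")
def full_model(geometry):
    """Full-genome chromatin model (6.4 Gbp default conditions)."""
    return build_nucleus_model(geometry, genome_length=6.4e9, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170327)
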