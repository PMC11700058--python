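import numpy as np
import pytest

from osteotrack import synthgen


@pytest.fixture(scope="session")
def trabecular_phantom():
    """Small GRF trabecular phantom shared across tests."""
    return synthgen.make_trabecular_phantom((48, 48, 48), 18.0, 0.25, seed=7)


@pytest.fixture(scope="session")
def annulus_coarse():
    """Annulus at a coarse voxel size for fast unit tests."""
    return synthgen.make_cortical_phantom(2.0, 1.0, voxel_size_um=20.0, n_slices=3)


@pytest.fixture(scope="session")
def pmma_ref():
    return synthgen.pmma_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
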