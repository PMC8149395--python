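import numpy as np
import pytest

import hippofc as h
from hippofc.meshes import make_grid_mesh


@pytest.fixture(scope="session")
def small_spec() -> h.PhantomSpec:
    """Desk-scale phantom: 6 parcels, 8 subjects, snr 2."""
    return h.PhantomSpec(n_subjects=8, snr=2.0, rng_seed=7)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return h.make_phantom(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec, small_truth):
    return h.simulate_cohort(small_truth, small_spec)


@pytest.fixture(scope="session")
def grid_mesh():
    """Regular planar mesh, 500 vertices at 1.5 mm spacing."""
    return make_grid_mesh(25, 20, spacing_mm=1.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
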