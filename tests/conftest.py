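import numpy as np
import pytest

from boundaryprofile.synthetic_cohort import (
    SyntheticSpec,
    make_template_geometry,
    simulate_cohort,
)
from boundaryprofile.vertex_glm import build_design


@pytest.fixture(scope="session")
def slab_spec():
    """30 mm slab at 1 mm spacing; 80 subjects (40 per group)."""
    return SyntheticSpec(mesh_extent_mm=30.0, vertex_spacing_mm=1.0,
                         n_per_cell=10, seed=12345)


@pytest.fixture(scope="session")
def slab_geometry(slab_spec):
    return make_template_geometry(slab_spec)


@pytest.fixture(scope="session")
def slab_white(slab_geometry):
    return slab_geometry[0]


@pytest.fixture(scope="session")
def cohort80(slab_spec):
    cohort, _truth = simulate_cohort(slab_spec)
    return cohort


@pytest.fixture(scope="session")
def design80(cohort80):
    return build_design(cohort80)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
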