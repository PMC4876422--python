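import numpy as np
import pytest

from epfem.fem_engine import SolverControls
from epfem.mesh_geometry import build_plate_box, build_two_needle_geometry
from epfem.params import TissueParameters


@pytest.fixture(scope="session")
def params():
    """Default fitted parameter set (beef liver, two-needle electrodes)."""
    return TissueParameters()


@pytest.fixture(scope="session")
def controls(params):
    return SolverControls.from_params(params)


@pytest.fixture(scope="session")
def plate_mesh():
    """Small plate-capacitor box: 10 mm gap, 1 cm^2 electrode area."""
    return build_plate_box(gap=0.01, area=1e-4, n_gap=3, n_side=3)


@pytest.fixture(scope="session")
def needle_mesh_coarse():
    """Minimal-count two-needle mesh (~2.8k tets) for iteration studies."""
    return build_two_needle_geometry(targetEdgeLength=5e-3,
                                     resolve_near_field=False)


@pytest.fixture(scope="session")
def needle_mesh():
    """Default-graded two-needle mesh at 5 mm bulk edge length."""
    return build_two_needle_geometry(targetEdgeLength=5e-3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
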