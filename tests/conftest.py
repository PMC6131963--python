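import numpy as np
import pytest

import frogpad as fp
from frogpad import fem

# desk resolution used for pad-model analyses in the suite: 0.05 mm voxels,
# the coarsest grid that still resolves the 0.1 mm duct holes
PAD_RESOLUTION = (30, 20, 9)
SHEAR_LOAD_N = 3.815e-3


@pytest.fixture(scope="session")
def material():
    return fp.Material(E_MPa=20.0, nu=0.33, sigma_t_MPa=20.0)


@pytest.fixture(scope="session")
def pad_params():
    return fp.PadGeometryParams()


@pytest.fixture(scope="session")
def pad_domain(pad_params):
    return fp.build_design_domain(pad_params, PAD_RESOLUTION)


@pytest.fixture(scope="session")
def shear_load_case():
    return fem.LoadCase(
        tractions=(fem.FaceTraction(face="proximal", force_N=(-SHEAR_LOAD_N, 0.0, 0.0)),)
    )


@pytest.fixture(scope="session")
def pad_solution(pad_domain, material, shear_load_case):
    """Solved non-optimised pad model under the proximal shear pull."""
    return fp.solve(pad_domain, material, shear_load_case)


@pytest.fixture(scope="session")
def pad_stress(pad_domain, material, pad_solution):
    return fp.recover_stress(pad_domain, material, pad_solution)


def uniform_stress_field(domain, tensor):
    """StressField with the same tensor in every voxel (synthetic test field)."""
    t = np.broadcast_to(np.asarray(tensor, float), (*domain.resolution, 3, 3)).copy()
    return fem.StressField(domain=domain, tensors=t, mask=domain.solid_mask.copy())
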