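import numpy as np
import pytest

from lapwsim.fibers import ConductivitySet, conductivity_tensor, template_field
from lapwsim.geometry import build_slab_mesh
from lapwsim.synthetic_data import (
    PseudoRecordingSpec,
    SheetSpec,
    make_electrode_grid,
    make_recorded_egm_set,
    make_sheet_pcd,
)


@pytest.fixture(scope="session")
def small_slab():
    """10×10×2.3 mm slab at 1 mm spacing (600 tets) — cheap solver runs."""
    return build_slab_mesh(10.0, 10.0, 1.0, 2.3, 0)


@pytest.fixture(scope="session")
def small_slab_field(small_slab):
    return template_field(small_slab, 0.0, 0.0)  # fibers along +x


@pytest.fixture(scope="session")
def small_slab_tensors(small_slab_field):
    return conductivity_tensor(small_slab_field, ConductivitySet())


@pytest.fixture(scope="session")
def slab_20mm():
    """The standard 20×20×2.3 mm slab at 1 mm spacing (2400 tets)."""
    return build_slab_mesh(20.0, 20.0, 1.0, 2.3, 0)


@pytest.fixture(scope="session")
def slab_20mm_field(slab_20mm):
    return template_field(slab_20mm, 0.0, 0.0)


@pytest.fixture(scope="session")
def flat_sheet_cloud():
    return make_sheet_pcd(SheetSpec(extent_x=20.0, extent_y=20.0, point_spacing=1.0, seed=0))


@pytest.fixture(scope="session")
def electrode_grid_20mm(flat_sheet_cloud):
    from lapwsim.geometry import reconstruct_surface

    surf = reconstruct_surface(flat_sheet_cloud)
    return make_electrode_grid(surf, 4.0, 1.0)


@pytest.fixture()
def clean_recording_set(electrode_grid_20mm):
    """Noiseless pseudo-recordings: exact LATs, identical waveshapes."""
    spec = PseudoRecordingSpec(
        cv=70.0, amplitude_sd=0.0, jitter_sd=0.0, fractionation_probability=0.0, seed=3
    )
    return make_recorded_egm_set(electrode_grid_20mm, spec)


def nn_distances(points: np.ndarray) -> np.ndarray:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(points).query(points, k=2)
    return d[:, 1]
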