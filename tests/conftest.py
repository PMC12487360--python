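import warnings

import numpy as np
import pytest
import trimesh

from fetalgrowth.surface_morphometry import CorticalMesh


@pytest.fixture(autouse=True)
def _quiet_missing_label_warnings():
    # phantoms legitimately omit several template labels
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="labels .* absent")
        yield


@pytest.fixture(scope="session")
def shell_phantom():
    from fetalgrowth.synthetic_data import make_phantom_labelmap

    return make_phantom_labelmap("concentric_shells")


@pytest.fixture(scope="session")
def shell_mesh(shell_phantom):
    from fetalgrowth.surface_morphometry import extract_midcortical_surface

    vol, _ = shell_phantom
    return extract_midcortical_surface(vol, "both")


def icosphere_mesh(radius=1.0, subdivisions=4) -> CorticalMesh:
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return CorticalMesh(np.asarray(s.vertices), np.asarray(s.faces))


@pytest.fixture(scope="session")
def unit_icosphere():
    return icosphere_mesh(1.0, 4)


@pytest.fixture(scope="session")
def default_cohort():
    from fetalgrowth.synthetic_data import simulate_cohort

    return simulate_cohort(seed=11)
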