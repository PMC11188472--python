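import numpy as np
import pytest

from ivdfem.geometry import DiscGeometryParams, build_disc
from ivdfem.model import MaterialConfig, build_disc_model


def random_deformation_gradient(rng, scale=0.15):
    """Random admissible deformation gradient near identity (det > 0)."""
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.3:
            return F


@pytest.fixture(scope="session")
def default_mesh():
    mesh, ref = build_disc(DiscGeometryParams())
    return mesh, ref


@pytest.fixture(scope="session")
def mini_geometry():
    """Smallest admissible disc mesh (budget-friendly forward solves)."""
    return DiscGeometryParams(n_theta=8, n_np_rings=1, n_z=2)


@pytest.fixture(scope="session")
def mini_hgo_model(mini_geometry):
    return build_disc_model(mini_geometry, MaterialConfig.median("hgo"))


@pytest.fixture(scope="session")
def mini_rebar_model(mini_geometry):
    return build_disc_model(mini_geometry,
                            MaterialConfig.median("linear_rebar"))
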