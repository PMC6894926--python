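import numpy as np
import pytest
import trimesh

from actionrsa import make_ground_truth, make_toy_surface
from actionrsa.models import ModelSet
from actionrsa.surface import SurfaceMesh


@pytest.fixture(scope="session")
def icosphere42() -> SurfaceMesh:
    """Smallest icosphere (42 vertices) for brute-force mesh oracles."""
    ico = trimesh.creation.icosphere(subdivisions=1, radius=1.0)
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces),
                       np.zeros(len(ico.vertices), dtype=int))


@pytest.fixture(scope="session")
def gt28():
    """28 items in 6 well-separated planted clusters."""
    return make_ground_truth(28, 6, cluster_spread=5.0, within_spread=0.6,
                             seed=7)


@pytest.fixture(scope="session")
def two_model_set(gt28) -> ModelSet:
    other = make_ground_truth(28, 6, cluster_spread=5.0, within_spread=0.6,
                              seed=8)
    return ModelSet({"semantic": gt28.true_rdm.copy(model="semantic"),
                     "body": other.true_rdm.copy(model="body")})


@pytest.fixture(scope="session")
def small_region_mesh() -> SurfaceMesh:
    return make_toy_surface(subdivisions=2, n_regions=1, region_size=30,
                            seed=0)
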