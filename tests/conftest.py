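import warnings

import numpy as np
import pytest
import trimesh
from hypothesis import settings

from spinemorph.synthetic import default_spec, make_synthetic_spine

warnings.filterwarnings("ignore", category=FutureWarning)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=3)


@pytest.fixture(scope="session")
def fine_icosphere():
    return trimesh.creation.icosphere(subdivisions=4)


@pytest.fixture(scope="session")
def unit_tube():
    """Straight tube spine: radius 1, side length 7, with domed caps."""
    from spinemorph.synthetic import SpineSpec
    spec = SpineSpec(neck_length=7.0, neck_radius=1.0, head_radius=1.0,
                     profile="straight_tube")
    return make_synthetic_spine(spec)


@pytest.fixture(scope="session")
def profile_meshes():
    """(mesh, insertion, truth) for each of the four built-in profiles."""
    return {p: make_synthetic_spine(default_spec(p))
            for p in ("stubby", "thin", "mushroom-like", "straight_tube")}


@pytest.fixture(scope="session")
def profile_model():
    from spinemorph.synthetic import profile_feature_model
    return profile_feature_model()


@pytest.fixture(scope="session")
def flat_disk():
    """Triangulated planar disk of radius 2 centred at the origin."""
    import scipy.spatial
    pts = [np.zeros(2)]
    for r in np.linspace(0, 2, 25)[1:]:
        n = max(6, int(2 * np.pi * r / 0.08))
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts.append(np.c_[r * np.cos(t), r * np.sin(t)])
    pts = np.vstack(pts)
    tri = scipy.spatial.Delaunay(pts)
    mesh = trimesh.Trimesh(np.c_[pts, np.zeros(len(pts))], tri.simplices,
                           process=False)
    return mesh
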