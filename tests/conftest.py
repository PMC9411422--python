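import warnings

import numpy as np
import pytest

from sphervert import mesh

warnings.filterwarnings("ignore", category=RuntimeWarning)

SPHERE_RADIUS = 270.0
SPHERE_AREA = 4.0 * np.pi * SPHERE_RADIUS ** 2


@pytest.fixture(scope="session")
def blastoderm64_master():
    return mesh.build_initial_blastoderm(
        mesh.InitMeshConfig(64, SPHERE_RADIUS, 50, 1))


@pytest.fixture
def blastoderm64(blastoderm64_master):
    return blastoderm64_master.copy()


@pytest.fixture(scope="session")
def mesh20_master():
    return mesh.build_initial_blastoderm(
        mesh.InitMeshConfig(20, SPHERE_RADIUS, 30, 2))


@pytest.fixture
def mesh20(mesh20_master):
    return mesh20_master.copy()


@pytest.fixture(scope="session")
def mesh200_master():
    return mesh.build_initial_blastoderm(
        mesh.InitMeshConfig(200, SPHERE_RADIUS, 30, 3))


@pytest.fixture
def mesh200(mesh200_master):
    return mesh200_master.copy()


def make_pillow(points, **cell_params):
    """A minimal closed mesh: one polygonal cell plus its mirror face
    over the same vertex ring (a two-faced 'pillow', Euler
    characteristic 2).  The mirror face carries zero moduli so only the
    front cell contributes energy."""
    from sphervert.core import EmbryoState
    st = EmbryoState()
    ids = [st.add_vertex(p, 0.0, max(np.linalg.norm(p), 1.0))
           for p in points]
    params = dict(alpha=1.0, gamma=0.0, area0=1.0, perim0=0.0, beta0=0.0)
    params.update(cell_params)
    front = st.add_cell(ids, **params)
    st.add_cell(ids[::-1], alpha=0.0, gamma=0.0, area0=0.0, beta0=0.0)
    return st, ids, front
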