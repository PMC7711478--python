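import numpy as np
import pytest

from enterospring.fem.mesh import HexMesh
from enterospring.materials import default_human_material_set


@pytest.fixture(scope="session")
def human_materials():
    return default_human_material_set()


def make_cube_mesh(n=2, L=2.0, perturb_interior=0.0, seed=3):
    """Structured n^3 brick mesh of an L^3 cube, optionally distorted.

    Returns (mesh, index dict (i,j,k)->node, boundary node list).
    """
    xs = np.linspace(0.0, L, n + 1)
    nodes, idx = [], {}
    c = 0
    for i in range(n + 1):
        for j in range(n + 1):
            for k in range(n + 1):
                nodes.append([xs[i], xs[j], xs[k]])
                idx[(i, j, k)] = c
                c += 1
    nodes = np.array(nodes, dtype=float)
    boundary = sorted({
        node for (i, j, k), node in idx.items()
        if 0 in (i, j, k) or n in (i, j, k)
    })
    if perturb_interior:
        rng = np.random.default_rng(seed)
        for node in range(len(nodes)):
            if node not in boundary:
                nodes[node] += perturb_interior * rng.standard_normal(3)
    elems = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                elems.append([
                    idx[(i, j, k)], idx[(i + 1, j, k)],
                    idx[(i + 1, j + 1, k)], idx[(i, j + 1, k)],
                    idx[(i, j, k + 1)], idx[(i + 1, j, k + 1)],
                    idx[(i + 1, j + 1, k + 1)], idx[(i, j + 1, k + 1)],
                ])
    mesh = HexMesh(
        nodes=nodes, elems=np.array(elems),
        layer_tags=np.array(["mucosa"] * len(elems)),
        node_sets={}, ties=[], z_length=L)
    return mesh, idx, boundary


@pytest.fixture
def cube_mesh():
    return make_cube_mesh(n=2, perturb_interior=0.13)
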