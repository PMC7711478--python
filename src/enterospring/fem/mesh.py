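"""Structured hexahedral mesh of the layered cylinder + mesentery sheet.

The distracted segment is a hollow cylinder (axis = Z) whose wall holds
three concentric layers (mucosa, submucosa, muscularis, inner to outer).
Axial symmetry of the two-ended loading is exploited: the mesh covers
half the segment, z in [0, L/2], with the symmetry plane at z = 0 (the
true mid-length) and the loaded end at z = L/2.

The mesentery is an optional rectangular sheet hanging radially off the
outer-wall generatrix at theta = 270 deg (pointing -y), spanning the
full axial extent. Its top edge is tied node-to-node to the outer wall;
its base edge is fixed by the boundary conditions.

All coordinates in mm. 8-node hexes, locally ordered so the reference
Jacobian is positive (VTK hexahedron ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..errors import MeshingError
from ..geometry import LAYER_NAMES, IntestineModelSpec


@dataclass(frozen=True)
class MeshResolution:
    """Element counts: per-layer radial, circumferential, axial (half model)."""

    n_r_per_layer: tuple[int, int, int] = (1, 1, 1)
    n_theta: int = 24
    n_z: int = 10
    n_mesentery_height: int = 4

    def refined(self, factor: int = 2) -> "MeshResolution":
        return MeshResolution(
            n_r_per_layer=tuple(n * factor for n in self.n_r_per_layer),
            n_theta=self.n_theta * factor,
            n_z=self.n_z * factor,
            n_mesentery_height=self.n_mesentery_height * factor,
        )


@dataclass
class HexMesh:
    """Hex mesh with layer tags, node sets and node-tie constraints."""

    nodes: np.ndarray  # (N, 3) mm
    elems: np.ndarray  # (E, 8) int
    layer_tags: np.ndarray  # (E,) unicode layer names
    node_sets: dict[str, np.ndarray]
    ties: list[tuple[int, int]] = field(default_factory=list)  # (slave, master)
    # structured bookkeeping for post-processing (cylinder part only)
    elem_part: np.ndarray | None = None  # 0 = cylinder, 1 = mesentery sheet
    elem_grid: np.ndarray | None = None  # (E, 3) (i_r, i_theta, i_z), -1 for sheet
    theta_nodes: np.ndarray | None = None
    z_length: float = 0.0  # meshed (half-segment) length, mm
    spec: IntestineModelSpec | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elems(self) -> int:
        return len(self.elems)


def _radial_nodes(spec: IntestineModelSpec, res: MeshResolution):
    """Radial node positions and per-radial-element layer names."""
    bounds = spec.radii_mm()
    rs = [np.array([bounds[0]])]
    tags = []
    for i, n in enumerate(res.n_r_per_layer):
        if n < 1:
            raise MeshingError("need >= 1 radial element per layer")
        seg = np.linspace(bounds[i], bounds[i + 1], n + 1)[1:]
        if seg[0] - rs[-1][-1] <= 0:
            raise MeshingError(
                f"degenerate layer {LAYER_NAMES[i]} at resolution {res}")
        rs.append(seg)
        tags.extend([LAYER_NAMES[i]] * n)
    return np.concatenate(rs), np.array(tags)


def build_mesh(spec: IntestineModelSpec, resolution: MeshResolution | None = None) -> HexMesh:
    """Mesh the half model of ``spec`` (with mesentery if configured)."""
    res = resolution or MeshResolution()
    if res.n_theta < 8 or res.n_theta % 4:
        raise MeshingError("n_theta must be >= 8 and a multiple of 4")
    if res.n_z < 1:
        raise MeshingError("n_z must be >= 1")

    radii, r_tags = _radial_nodes(spec, res)
    n_r = len(radii) - 1
    n_t, n_z = res.n_theta, res.n_z
    theta = 2.0 * np.pi * np.arange(n_t) / n_t
    L_half = spec.segment_length_mm / 2.0
    z = np.linspace(0.0, L_half, n_z + 1)

    # --- cylinder nodes -------------------------------------------------
    def nid(ir, jt, kz):
        return (ir * n_t + (jt % n_t)) * (n_z + 1) + kz

    R, T, Z = np.meshgrid(radii, theta, z, indexing="ij")
    nodes = np.column_stack([
        (R * np.cos(T)).ravel(), (R * np.sin(T)).ravel(), Z.ravel()])

    elems, tags, grid = [], [], []
    for ir in range(n_r):
        for jt in range(n_t):
            for kz in range(n_z):
                elems.append([
                    nid(ir, jt, kz), nid(ir + 1, jt, kz),
                    nid(ir + 1, jt + 1, kz), nid(ir, jt + 1, kz),
                    nid(ir, jt, kz + 1), nid(ir + 1, jt, kz + 1),
                    nid(ir + 1, jt + 1, kz + 1), nid(ir, jt + 1, kz + 1),
                ])
                tags.append(r_tags[ir])
                grid.append((ir, jt, kz))

    n_cyl_nodes = len(nodes)
    node_sets = {
        "inner_surface": np.array(
            [nid(0, jt, kz) for jt in range(n_t) for kz in range(n_z + 1)]),
        "end_z0": np.array(
            [nid(ir, jt, 0) for ir in range(n_r + 1) for jt in range(n_t)]),
        "end_zL": np.array(
            [nid(ir, jt, n_z) for ir in range(n_r + 1) for jt in range(n_t)]),
    }
    ties: list[tuple[int, int]] = []
    part = [0] * len(elems)

    # --- mesentery sheet -------------------------------------------------
    if spec.mesentery is not None:
        mes = spec.mesentery
        h = mes.resolved_height_mm(spec.inner_radius)
        tk = mes.thickness_mm
        if tk <= 0:
            raise MeshingError("mesentery thickness must be > 0")
        n_h = max(1, res.n_mesentery_height)
        j_att = 3 * n_t // 4  # theta = 270 deg -> (0, -r)
        r_out = radii[-1]

        ys = -(r_out + h * np.arange(n_h + 1) / n_h)
        xs = np.array([-tk / 2.0, tk / 2.0])
        sheet_ids = np.empty((n_h + 1, 2, n_z + 1), dtype=int)
        sheet_nodes = []
        nxt = n_cyl_nodes
        for ih in range(n_h + 1):
            for ix in range(2):
                for kz in range(n_z + 1):
                    sheet_nodes.append([xs[ix], ys[ih], z[kz]])
                    sheet_ids[ih, ix, kz] = nxt
                    nxt += 1
        nodes = np.vstack([nodes, np.array(sheet_nodes)])

        # tie sheet top edge to the outer-wall generatrix at theta=270
        for ix in range(2):
            for kz in range(n_z + 1):
                ties.append((int(sheet_ids[0, ix, kz]), nid(n_r, j_att, kz)))

        # local axes: xi -> -y (downwards), eta -> +x, zeta -> +z (det > 0)
        for ih in range(n_h):
            for kz in range(n_z):
                elems.append([
                    sheet_ids[ih, 0, kz], sheet_ids[ih + 1, 0, kz],
                    sheet_ids[ih + 1, 1, kz], sheet_ids[ih, 1, kz],
                    sheet_ids[ih, 0, kz + 1], sheet_ids[ih + 1, 0, kz + 1],
                    sheet_ids[ih + 1, 1, kz + 1], sheet_ids[ih, 1, kz + 1],
                ])
                tags.append("mesentery")
                grid.append((-1, -1, kz))
                part.append(1)

        node_sets["mesentery_base"] = sheet_ids[n_h].ravel()
        node_sets["end_z0"] = np.concatenate(
            [node_sets["end_z0"], sheet_ids[1:, :, 0].ravel()])

    mesh = HexMesh(
        nodes=np.asarray(nodes, dtype=float),
        elems=np.asarray(elems, dtype=np.int64),
        layer_tags=np.asarray(tags),
        node_sets={k: np.unique(v) for k, v in node_sets.items()},
        ties=ties,
        elem_part=np.asarray(part, dtype=np.int8),
        elem_grid=np.asarray(grid, dtype=np.int64),
        theta_nodes=theta,
        z_length=L_half,
        spec=spec,
    )
    jac = reference_jacobians(mesh)
    if np.any(jac <= 0):
        raise MeshingError("non-positive reference Jacobian in mesh")
    return mesh


#: 2x2x2 Gauss abscissa
_GP = 1.0 / np.sqrt(3.0)
#: local corner coordinates, VTK hexahedron ordering
_CORNERS = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)


def gauss_points() -> np.ndarray:
    """(8, 3) Gauss point local coordinates (weights are all 1)."""
    pts = []
    for zeta in (-_GP, _GP):
        for eta in (-_GP, _GP):
            for xi in (-_GP, _GP):
                pts.append((xi, eta, zeta))
    return np.array(pts)


def shape_gradients_local(points: np.ndarray) -> np.ndarray:
    """dN_a/dxi at given local points: (G, 8, 3)."""
    G = len(points)
    out = np.empty((G, 8, 3))
    for g, (xi, eta, zeta) in enumerate(points):
        for a, (xa, ea, za) in enumerate(_CORNERS):
            out[g, a, 0] = 0.125 * xa * (1 + ea * eta) * (1 + za * zeta)
            out[g, a, 1] = 0.125 * ea * (1 + xa * xi) * (1 + za * zeta)
            out[g, a, 2] = 0.125 * za * (1 + xa * xi) * (1 + ea * eta)
    return out


def shape_functions(points: np.ndarray) -> np.ndarray:
    """N_a at given local points: (G, 8)."""
    out = np.empty((len(points), 8))
    for g, (xi, eta, zeta) in enumerate(points):
        out[g] = 0.125 * (1 + _CORNERS[:, 0] * xi) \
            * (1 + _CORNERS[:, 1] * eta) * (1 + _CORNERS[:, 2] * zeta)
    return out


def reference_jacobians(mesh: HexMesh) -> np.ndarray:
    """det(dX/dxi) at every Gauss point: (E, 8)."""
    dN = shape_gradients_local(gauss_points())  # (G,8,3)
    Xe = mesh.nodes[mesh.elems]  # (E,8,3)
    Jmap = np.einsum("gai,eaj->egij", dN, Xe)  # dX_j/dxi_i
    return np.linalg.det(Jmap)


def element_layer_arrays(
    mesh: HexMesh, materials: Mapping[str, object]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element (C, D) arrays from a {layer name: LayerMaterial} map."""
    C = np.empty(mesh.n_elems)
    D = np.empty(mesh.n_elems)
    for name in np.unique(mesh.layer_tags):
        m = materials[str(name)]
        sel = mesh.layer_tags == name
        C[sel] = m.C
        D[sel] = m.D
    return C, D
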