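"""Constraint handling and the incremental Newton solver.

Displacements are driven at the loaded end (z = L/2 of the half model)
while the symmetry plane (z = 0, the segment mid-length) is held
axially. Constraints are eliminated exactly through a sparse
transformation u = T q + lambda * g, where q are the reduced unknowns,
g carries the prescribed displacement pattern and lambda in [0, 1] is
the load factor:

* fixed / prescribed Cartesian components drop out of T;
* inner-surface nodes are rotated to a cylindrical basis so the
  "no twist" condition (u_theta = 0, motivated by the spring's contact
  with the mucosa) is a plain single-dof fix while radial and axial
  motion stay free;
* mesentery-sheet top nodes are tied rigidly to their outer-wall
  master nodes (node merging).

Each load increment is solved by full Newton with the complex-step
consistent tangent; divergence triggers automatic step halving (at most
4 times).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from ..errors import ConfigurationError, SolverFailureError
from ..geometry import IntestineModelSpec
from .assembly import Precomputed, assemble_tangent, internal_force, precompute
from .mesh import HexMesh, MeshResolution, build_mesh, element_layer_arrays


@dataclass
class BoundaryConditionSet:
    """Declarative BCs applied to named node sets.

    ``fixed`` maps a node-set name to a component string ("z", "xyz"...);
    ``prescribed`` maps a node-set name to (component, displacement) —
    the displacement is reached at load factor 1. ``pins`` are extra
    single-node component fixes used to suppress rigid-body modes when
    neither the inner-surface constraint nor the mesentery anchors the
    section. ``inner_no_twist`` activates u_theta = 0 on the inner
    surface.
    """

    fixed: dict[str, str] = field(default_factory=dict)
    prescribed: dict[str, tuple[str, float]] = field(default_factory=dict)
    inner_no_twist: bool = True
    pins: list[tuple[int, str]] = field(default_factory=list)
    #: per-node prescribed values (node, component, displacement) — used
    #: e.g. for affine patch-test boundary displacements
    nodal_prescribed: list[tuple[int, str, float]] = field(default_factory=list)


def default_bcs(mesh: HexMesh, end_displacement: float,
                inner_no_twist: bool = True) -> BoundaryConditionSet:
    """The standard loading: symmetry at z=0, prescribed uz at z=L/2.

    The mesentery base (when present) is fully fixed. Without both the
    mesentery and the inner no-twist constraint, three tangential pins
    suppress the in-plane rigid modes without blocking radial motion.
    """
    bcs = BoundaryConditionSet(inner_no_twist=inner_no_twist)
    bcs.fixed["end_z0"] = "z"
    bcs.prescribed["end_zL"] = ("z", float(end_displacement))
    has_mes = "mesentery_base" in mesh.node_sets
    if has_mes:
        bcs.fixed["mesentery_base"] = "xyz"
    if not inner_no_twist and not has_mes:
        bcs.pins = _tangential_pins(mesh)
    return bcs


def _tangential_pins(mesh: HexMesh) -> list[tuple[int, str]]:
    """Tangential single-component pins at theta = 0, 90, 180 (inner, z=0)."""
    pins = []
    nt = len(mesh.theta_nodes)
    inner = mesh.node_sets["inner_surface"]
    z0 = set(mesh.node_sets["end_z0"].tolist())
    for j, comp in ((0, "y"), (nt // 4, "x"), (nt // 2, "y")):
        theta = mesh.theta_nodes[j]
        target = None
        for n in inner:
            if n not in z0:
                continue
            x, y = mesh.nodes[n, 0], mesh.nodes[n, 1]
            ang = np.arctan2(y, x) % (2 * np.pi)
            if abs(ang - theta) < 1e-9:
                target = int(n)
                break
        if target is None:
            raise ConfigurationError("pin node not found on inner surface")
        pins.append((target, comp))
    return pins


_COMP = {"x": 0, "y": 1, "z": 2}


@dataclass
class ConstraintSystem:
    """u = T q + load_factor * g."""

    T: sparse.csr_matrix
    g: np.ndarray
    n_reduced: int


def build_constraints(mesh: HexMesh, bcs: BoundaryConditionSet) -> ConstraintSystem:
    n = mesh.n_nodes
    # per-node local basis (3x3 columns = local directions) and per-local-dir
    # status: 0 free, 1 fixed, 2 prescribed(value)
    basis = np.tile(np.eye(3), (n, 1, 1))
    status = np.zeros((n, 3), dtype=np.int8)
    value = np.zeros((n, 3))

    rotated = np.zeros(n, dtype=bool)
    if bcs.inner_no_twist and "inner_surface" in mesh.node_sets:
        for node in mesh.node_sets["inner_surface"]:
            x, y = mesh.nodes[node, 0], mesh.nodes[node, 1]
            r = np.hypot(x, y)
            er = np.array([x / r, y / r, 0.0])
            et = np.array([-y / r, x / r, 0.0])
            basis[node] = np.column_stack([er, et, [0, 0, 1]])
            status[node, 1] = 1  # u_theta = 0
            rotated[node] = True

    def apply(node: int, comp: str, st: int, val: float = 0.0):
        c = _COMP[comp]
        if rotated[node] and c != 2:
            raise ConfigurationError(
                "cannot fix Cartesian x/y on a cylindrical-rotated node")
        # on rotated nodes local dir 2 is e_z == Cartesian z
        if status[node, c] == 2 and st == 1:
            raise ConfigurationError(
                f"node {node} component {comp} both fixed and prescribed")
        if st == 2 and status[node, c] == 1:
            raise ConfigurationError(
                f"node {node} component {comp} both fixed and prescribed")
        status[node, c] = max(status[node, c], st)
        if st == 2:
            value[node, c] = val

    for set_name, comps in bcs.fixed.items():
        for node in mesh.node_sets[set_name]:
            for comp in comps:
                apply(int(node), comp, 1)
    for set_name, (comp, val) in bcs.prescribed.items():
        for node in mesh.node_sets[set_name]:
            apply(int(node), comp, 2, val)
    for node, comp in bcs.pins:
        apply(int(node), comp, 1)
    for node, comp, val in bcs.nodal_prescribed:
        apply(int(node), comp, 2, val)

    slaves = {s: m for s, m in mesh.ties}
    if set(slaves) & {m for _, m in mesh.ties}:
        raise ConfigurationError("chained ties are not supported")

    # assign reduced columns to master (non-slave) nodes
    col_of = -np.ones((n, 3), dtype=np.int64)
    nq = 0
    for node in range(n):
        if node in slaves:
            continue
        for c in range(3):
            if status[node, c] == 0:
                col_of[node, c] = nq
                nq += 1

    rows, cols, vals = [], [], []
    g = np.zeros(3 * n)

    def emit(node: int, src: int):
        """Write node's 3 Cartesian dof rows from source node's basis/status."""
        for c in range(3):
            d = basis[src][:, c]
            if status[src, c] == 0:
                q = col_of[src, c]
                for i in range(3):
                    if d[i] != 0.0:
                        rows.append(3 * node + i)
                        cols.append(q)
                        vals.append(d[i])
            elif status[src, c] == 2:
                g[3 * node: 3 * node + 3] += value[src, c] * d

    for node in range(n):
        emit(node, slaves.get(node, node))

    T = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(3 * n, nq)).tocsr()
    return ConstraintSystem(T=T, g=g, n_reduced=nq)


@dataclass
class SolverOptions:
    n_increments: int = 5
    newton_rtol: float = 1e-9
    newton_atol: float = 1e-9  # N
    max_iterations: int = 30
    max_halvings: int = 4
    verbose: bool = False


@dataclass
class SolutionField:
    """Converged displacement field and reaction bookkeeping."""

    mesh: HexMesh
    u: np.ndarray  # (N, 3) mm
    reaction_end: float  # axial reaction at the loaded end, N
    reaction_symmetry: float  # axial reaction at the symmetry plane, N
    converged: bool
    increments: list[dict]
    C_e: np.ndarray
    D_e: np.ndarray
    pre: Precomputed


def _axial_reaction(mesh: HexMesh, f_full: np.ndarray, set_name: str) -> float:
    nodes = mesh.node_sets.get(set_name)
    if nodes is None or len(nodes) == 0:
        return 0.0
    return float(f_full[3 * nodes + 2].sum())


def solve_static(
    mesh: HexMesh,
    bcs: BoundaryConditionSet,
    materials: Mapping[str, object],
    options: SolverOptions | None = None,
    ramp: np.ndarray | None = None,
) -> SolutionField:
    """Incremental Newton solution under the given BCs.

    ``ramp`` (3N, optional) is a smooth displacement field at load
    factor 1 used as the predictor for each increment (projected onto
    the constraint space, so it never violates BCs). Without it the
    increment starts from the previous state plus the raw prescribed
    jump, which can transiently invert elements next to the loaded end
    on fine meshes.

    Raises :class:`SolverFailureError` (with per-increment diagnostics)
    if an increment fails to converge after the allowed step halvings.
    """
    opt = options or SolverOptions()
    C_e, D_e = element_layer_arrays(mesh, materials)
    if np.any(D_e <= 0):
        raise ConfigurationError(
            "FEM requires D > 0 (nu < 0.5); use nu = 0.49 for near-incompressibility")
    pre = precompute(mesh)
    cons = build_constraints(mesh, bcs)
    T, g = cons.T, cons.g
    Tt = T.T.tocsr()

    q = np.zeros(cons.n_reduced)
    # least-squares projection of the predictor onto the reduced space
    w = None
    if ramp is not None:
        TtT = (Tt @ T).tocsc()
        w = spsolve(TtT, Tt @ (np.asarray(ramp).ravel() - g))
    lam, dlam = 0.0, 1.0 / opt.n_increments
    halvings = 0
    history: list[dict] = []
    t0 = time.perf_counter()

    while lam < 1.0 - 1e-12:
        lam_try = min(1.0, lam + dlam)
        q_try = q.copy()
        if w is not None:
            q_try = q_try + (lam_try - lam) * w
        ok, iters, res_log = _newton(
            mesh, pre, T, Tt, g, lam_try, q_try, C_e, D_e, opt)
        if ok:
            q, lam = q_try, lam_try
            history.append({"lambda": lam, "iterations": iters,
                            "residuals": res_log})
            if opt.verbose:
                print(f"  increment lambda={lam:.4f} converged in {iters} its")
            halvings = 0  # a success resets the halving budget
            # grow the step back after an easy increment
            if iters <= 6:
                dlam = min(dlam * 1.5, 1.0 / opt.n_increments)
        else:
            halvings += 1
            dlam /= 2.0
            history.append({"lambda_failed": lam_try, "iterations": iters,
                            "residuals": res_log})
            if halvings > opt.max_halvings:
                raise SolverFailureError(
                    f"no convergence at load factor {lam_try:.4f} after "
                    f"{opt.max_halvings} step halvings",
                    diagnostics={"history": history})

    u = (T @ q + g).reshape(-1, 3)
    f_full = internal_force(mesh, pre, u, C_e, D_e)
    sol = SolutionField(
        mesh=mesh, u=u,
        reaction_end=_axial_reaction(mesh, f_full, "end_zL"),
        reaction_symmetry=_axial_reaction(mesh, f_full, "end_z0"),
        converged=True, increments=history, C_e=C_e, D_e=D_e, pre=pre)
    if opt.verbose:
        print(f"  solve time {time.perf_counter() - t0:.2f} s, "
              f"reaction {sol.reaction_end:.4f} N")
    return sol


def _newton(mesh, pre, T, Tt, g, lam, q, C_e, D_e, opt) -> tuple[bool, int, list]:
    res_log: list[float] = []
    r0 = None

    def residual(q_at):
        u = (T @ q_at + lam * g).reshape(-1, 3)
        return Tt @ internal_force(mesh, pre, u, C_e, D_e), u

    try:
        r, u = residual(q)
    except Exception:
        return False, 0, res_log
    for it in range(opt.max_iterations):
        rn = float(np.linalg.norm(r))
        res_log.append(rn)
        if not np.isfinite(rn):
            return False, it, res_log
        if r0 is None:
            r0 = max(rn, 1e-30)
        if rn < max(opt.newton_atol, opt.newton_rtol * r0):
            return True, it, res_log
        if rn > 1e4 * r0 and it > 3:
            return False, it, res_log
        K = assemble_tangent(mesh, pre, u, C_e, D_e)
        K_red = (Tt @ K @ T).tocsc()
        try:
            dq = spsolve(K_red, -r)
        except Exception:
            return False, it, res_log
        if not np.all(np.isfinite(dq)):
            return False, it, res_log
        # backtrack on element inversion (transient overshoot)
        step = 1.0
        for _ in range(6):
            try:
                r, u = residual(q + step * dq)
            except Exception:
                step *= 0.5
                continue
            q += step * dq
            break
        else:
            return False, it, res_log
    return False, opt.max_iterations, res_log


@dataclass
class DoublingResult:
    force: float  # N, total axial reaction at the loaded end
    solution: SolutionField
    mesh: HexMesh
    resolution: MeshResolution


def find_doubling_force(
    spec: IntestineModelSpec,
    materials: Mapping[str, object],
    resolution: MeshResolution | None = None,
    stretch: float = 2.0,
    options: SolverOptions | None = None,
    inner_no_twist: bool = True,
) -> DoublingResult:
    """Axial force (N) that stretches the segment end-to-end by ``stretch``.

    Displacement-controlled: the half model's loaded end is driven to
    (stretch - 1) * L/2 and the force is the axial reaction there
    (equal and opposite to the symmetry-plane reaction when no
    mesentery shares the load path).
    """
    if stretch <= 1.0:
        raise ConfigurationError(f"stretch must exceed 1, got {stretch}")
    res = resolution or MeshResolution()
    mesh = build_mesh(spec, res)
    end_disp = (stretch - 1.0) * mesh.z_length
    bcs = default_bcs(mesh, end_disp, inner_no_twist=inner_no_twist)
    # predictor: homogeneous axial extension plus the isochoric radial
    # contraction 1/sqrt(stretch) (the incompressible uniaxial solution)
    ramp = np.zeros_like(mesh.nodes)
    ramp[:, 2] = end_disp * mesh.nodes[:, 2] / mesh.z_length
    ramp[:, :2] = (stretch ** -0.5 - 1.0) * mesh.nodes[:, :2]
    sol = solve_static(mesh, bcs, materials, options, ramp=ramp.ravel())
    return DoublingResult(force=sol.reaction_end, solution=sol,
                          mesh=mesh, resolution=res)


def check_mesh_convergence(
    spec: IntestineModelSpec,
    materials: Mapping[str, object],
    resolution: MeshResolution | None = None,
    stretch: float = 2.0,
    options: SolverOptions | None = None,
) -> dict:
    """Reaction change under uniform mesh halving (h -> h/2).

    Returns the coarse and refined forces and their relative change;
    the model is considered converged when the change is below 1%.
    """
    res = resolution or MeshResolution()
    coarse = find_doubling_force(spec, materials, res, stretch, options)
    fine = find_doubling_force(spec, materials, res.refined(), stretch, options)
    rel = abs(fine.force - coarse.force) / abs(fine.force)
    return {"force_coarse": coarse.force, "force_fine": fine.force,
            "relative_change": rel, "converged": rel < 0.01}
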