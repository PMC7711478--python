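"""Post-processing: Gauss-point fields and through-thickness wall profiles.

Strain and stress are reported in cylindrical components (R, theta, Z)
of the reference configuration — the natural frame of the tube. E is
the Lagrangian strain (F^T F - I)/2; S is the Cauchy stress computed
with the same mean-dilatation volumetric treatment as the solver.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import QueryError
from .assembly import deformation_gradients, mean_dilatation
from .mesh import gauss_points, shape_functions
from .solver import SolutionField


def gauss_point_fields(sol: SolutionField) -> dict[str, np.ndarray]:
    """F, E, Cauchy stress, position and displacement at every Gauss point.

    Shapes: X/u (E, G, 3); F/E_lag/sigma (E, G, 3, 3).
    """
    mesh, pre = sol.mesh, sol.pre
    u_e = sol.u[mesh.elems]
    X_e = mesh.nodes[mesh.elems]
    N = pre.N_gp  # (G, 8)
    X_gp = np.einsum("ga,eai->egi", N, X_e)
    u_gp = np.einsum("ga,eai->egi", N, u_e)

    F = deformation_gradients(pre, u_e)
    J = np.linalg.det(F)
    Jbar = mean_dilatation(pre, J)
    E_lag = 0.5 * (np.einsum("egki,egkj->egij", F, F) - np.eye(3))

    B = np.einsum("egik,egjk->egij", F, F)
    Jm23 = np.power(J, -2.0 / 3.0)
    B_bar = Jm23[..., None, None] * B
    trB = np.trace(B_bar, axis1=-2, axis2=-1)
    dev = B_bar - (trB / 3.0)[..., None, None] * np.eye(3)
    sigma = (2.0 * sol.C_e[:, None, None, None] / J[..., None, None]) * dev
    Up = (Jbar - 1.0 / Jbar) / sol.D_e
    sigma = sigma + (Up[:, None] * (np.ones_like(J)))[..., None, None] * np.eye(3)
    return {"X": X_gp, "u": u_gp, "F": F, "J": J, "E": E_lag, "sigma": sigma}


def _cylindrical_rotation(X: np.ndarray) -> np.ndarray:
    """Rotation matrices Q with columns (e_r, e_theta, e_z) at points X."""
    theta = np.arctan2(X[..., 1], X[..., 0])
    c, s = np.cos(theta), np.sin(theta)
    Q = np.zeros(X.shape[:-1] + (3, 3))
    Q[..., 0, 0] = c
    Q[..., 1, 0] = s
    Q[..., 0, 1] = -s
    Q[..., 1, 1] = c
    Q[..., 2, 2] = 1.0
    return Q


def extract_wall_profiles(
    sol: SolutionField,
    theta: float = np.pi / 2,
    z_ring: int = 0,
) -> pd.DataFrame:
    """Radial profiles across the wall thickness at mid-length.

    Samples the column of cylinder elements nearest the requested
    ``theta`` (default pi/2, the anti-mesenteric side) in axial element
    ring ``z_ring`` (default 0 — adjacent to the symmetry plane, i.e.
    the true mid-length of the distracted segment, away from the loaded
    end). Gauss values at equal radial stations are averaged over the
    circumferential/axial directions.

    Columns: r_mm, layer, u_mag_mm, E_RR, E_TT, E_ZZ, S_RR, S_TT, S_ZZ,
    ordered inner wall to outer wall.
    """
    mesh = sol.mesh
    if mesh.elem_grid is None:
        raise QueryError("mesh carries no structured bookkeeping")
    cyl = mesh.elem_part == 0
    n_t = len(mesh.theta_nodes)
    if z_ring < 0 or z_ring >= mesh.elem_grid[cyl][:, 2].max() + 1:
        raise QueryError(f"z_ring {z_ring} outside the mesh")
    # element column whose centre angle is nearest to theta
    centers = mesh.theta_nodes + np.pi / n_t
    j_sel = int(np.argmin(np.abs(np.angle(np.exp(1j * (centers - theta))))))

    sel = cyl & (mesh.elem_grid[:, 1] == j_sel) & (mesh.elem_grid[:, 2] == z_ring)
    if not np.any(sel):
        raise QueryError("no elements match the requested profile line")
    fields = gauss_point_fields(sol)
    X = fields["X"][sel]
    u = fields["u"][sel]
    E = fields["E"][sel]
    S = fields["sigma"][sel]
    Q = _cylindrical_rotation(X)
    E_cyl = np.einsum("egki,egkl,eglj->egij", Q, E, Q)
    S_cyl = np.einsum("egki,egkl,eglj->egij", Q, S, Q)
    r = np.hypot(X[..., 0], X[..., 1])
    u_mag = np.linalg.norm(u, axis=-1)

    # radial station: Gauss points alternate in xi (radial) fastest
    ir = mesh.elem_grid[sel][:, 0]
    g_rad = np.arange(8) % 2
    rows = []
    for e in range(sel.sum()):
        for station in (0, 1):
            gsel = g_rad == station
            rows.append({
                "i_radial": 2 * ir[e] + station,
                "r_mm": r[e, gsel].mean(),
                "layer": str(mesh.layer_tags[np.nonzero(sel)[0][e]]),
                "u_mag_mm": u_mag[e, gsel].mean(),
                "E_RR": E_cyl[e, gsel, 0, 0].mean(),
                "E_TT": E_cyl[e, gsel, 1, 1].mean(),
                "E_ZZ": E_cyl[e, gsel, 2, 2].mean(),
                "S_RR": S_cyl[e, gsel, 0, 0].mean(),
                "S_TT": S_cyl[e, gsel, 1, 1].mean(),
                "S_ZZ": S_cyl[e, gsel, 2, 2].mean(),
            })
    df = pd.DataFrame(rows).sort_values("r_mm").reset_index(drop=True)
    return df.drop(columns=["i_radial"])
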