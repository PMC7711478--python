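"""Total-Lagrangian internal forces and tangents for the neo-Hookean hex.

The element energy uses a mean-dilatation (B-bar) split to avoid
volumetric locking of trilinear hexes at nu = 0.49:

    Pi_e = sum_g w_g C (I1_bar(F_g) - 3)  +  V_e U(J_bar_e)

where I1_bar is the isochoric invariant evaluated at the 2x2x2 Gauss
points, U(J) = (1/D)[(J^2-1)/2 - ln J] is the volumetric energy and
J_bar_e = (integral of J over the element) / V_e is the element-mean
dilatation. The exact gradient gives the effective first Piola stress

    P_g = 2 C J^(-2/3) (F - (I1/3) F^-T)  +  U'(J_bar) J_g F_g^-T

(the volumetric part couples Gauss points only through the element
scalar J_bar). Element tangents are complex-step derivatives of this
analytic force — exact to machine precision, hence consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ..errors import InvertedElementError
from .mesh import HexMesh, gauss_points, shape_functions, shape_gradients_local

_CS_H = 1e-30  # complex-step size; no subtractive cancellation


@dataclass
class Precomputed:
    """Reference-configuration quantities reused across iterations."""

    gradN: np.ndarray   # (E, G, 8, 3) shape gradients wrt X
    dV: np.ndarray      # (E, G) Gauss weights x det(dX/dxi)
    V_e: np.ndarray     # (E,) element volumes
    dof_idx: np.ndarray  # (E, 24) global dof indices (x0,y0,z0, x1,...)
    N_gp: np.ndarray    # (G, 8) shape functions at Gauss points


def precompute(mesh: HexMesh) -> Precomputed:
    gp = gauss_points()
    dN_loc = shape_gradients_local(gp)  # (G,8,3)
    Xe = mesh.nodes[mesh.elems]  # (E,8,3)
    Jmap = np.einsum("gai,eaj->egij", dN_loc, Xe)  # dX_j/dxi_i
    detJ = np.linalg.det(Jmap)
    if np.any(detJ <= 0):
        raise InvertedElementError("non-positive reference Jacobian")
    # with M[i,j] = dX_j/dxi_i, the matrix dxi_i/dX_j is inv(M^T)^T = inv(M)
    # read with swapped indices: dxi_i/dX_j = inv(M)[j, i]... verify via
    # delta_ij = sum_k (dxi_i/dX_k)(dX_k/dxi_j), i.e. B M^T = I, B = inv(M^T)
    Jinv_T = np.linalg.inv(Jmap.swapaxes(-1, -2))  # B[e,g,i,j] = dxi_i/dX_j
    # gradN[e,g,a,j] = dN_a/dX_j = sum_i dN_a/dxi_i * B[i,j]
    gradN = np.einsum("gai,egij->egaj", dN_loc, Jinv_T)
    dV = detJ  # all 2x2x2 Gauss weights are 1
    V_e = dV.sum(axis=1)
    dof = (3 * mesh.elems[:, :, None] + np.arange(3)[None, None, :])
    return Precomputed(gradN=gradN, dV=dV, V_e=V_e,
                       dof_idx=dof.reshape(len(mesh.elems), 24),
                       N_gp=shape_functions(gp))


def deformation_gradients(pre: Precomputed, u_e: np.ndarray) -> np.ndarray:
    """F at every Gauss point: (E, G, 3, 3). u_e is (E, 8, 3)."""
    F = np.einsum("eai,egaj->egij", u_e, pre.gradN)
    F = F + np.eye(3, dtype=F.dtype)
    return F


def mean_dilatation(pre: Precomputed, J: np.ndarray) -> np.ndarray:
    """Element-mean volume ratio J_bar: (E,)."""
    return (J * pre.dV).sum(axis=1) / pre.V_e


def effective_piola(
    pre: Precomputed, u_e: np.ndarray, C_e: np.ndarray, D_e: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Effective PK1 stress (E,G,3,3), J (E,G) and J_bar (E,).

    Works for real or complex ``u_e`` (the complex path feeds the
    complex-step tangent).
    """
    F = deformation_gradients(pre, u_e)
    J = np.linalg.det(F)
    if not np.iscomplexobj(u_e) and np.any(J.real <= 0):
        raise InvertedElementError("element inverted (det F <= 0)")
    Jbar = mean_dilatation(pre, J)
    Finv_T = np.linalg.inv(F).swapaxes(-1, -2)
    I1 = np.einsum("egij,egij->eg", F, F)
    Jm23 = np.power(J, -2.0 / 3.0)
    P = 2.0 * C_e[:, None, None, None] * Jm23[..., None, None] * (
        F - (I1 / 3.0)[..., None, None] * Finv_T)
    # U'(J) = (1/D)(J - 1/J), evaluated at the element mean
    Up = (Jbar - 1.0 / Jbar) / D_e
    P = P + (Up[:, None] * J)[..., None, None] * Finv_T
    return P, J, Jbar


def element_internal_forces(
    pre: Precomputed, u_e: np.ndarray, C_e: np.ndarray, D_e: np.ndarray
) -> np.ndarray:
    """Element internal force vectors (E, 8, 3)."""
    P, _, _ = effective_piola(pre, u_e, C_e, D_e)
    return np.einsum("eg,egij,egaj->eai", pre.dV, P, pre.gradN)


def internal_force(
    mesh: HexMesh, pre: Precomputed, u: np.ndarray,
    C_e: np.ndarray, D_e: np.ndarray,
) -> np.ndarray:
    """Assembled internal force, shape (3 * n_nodes,). u is (N, 3)."""
    u_e = u[mesh.elems]
    f_e = element_internal_forces(pre, u_e, C_e, D_e)
    f = np.zeros(3 * mesh.n_nodes)
    np.add.at(f, pre.dof_idx.ravel(), f_e.reshape(-1, 24).ravel())
    return f


def total_energy(
    mesh: HexMesh, pre: Precomputed, u: np.ndarray,
    C_e: np.ndarray, D_e: np.ndarray,
) -> float | complex:
    """Total strain energy (mJ); supports complex u for step checks."""
    u_e = u[mesh.elems]
    F = deformation_gradients(pre, u_e)
    J = np.linalg.det(F)
    Jbar = mean_dilatation(pre, J)
    I1 = np.einsum("egij,egij->eg", F, F)
    W_dev = C_e[:, None] * (np.power(J, -2.0 / 3.0) * I1 - 3.0)
    U_vol = (0.5 * (Jbar * Jbar - 1.0) - np.log(Jbar)) / D_e
    total = (W_dev * pre.dV).sum() + (U_vol * pre.V_e).sum()
    return total if np.iscomplexobj(u) else float(total)


def element_tangents(
    mesh: HexMesh, pre: Precomputed, u: np.ndarray,
    C_e: np.ndarray, D_e: np.ndarray,
) -> np.ndarray:
    """Consistent element stiffness (E, 24, 24) by complex step."""
    u_e = u[mesh.elems].astype(complex)
    E = len(mesh.elems)
    K = np.empty((E, 24, 24))
    for j in range(24):
        a, i = divmod(j, 3)
        u_p = u_e.copy()
        u_p[:, a, i] += 1j * _CS_H
        f = element_internal_forces(pre, u_p, C_e, D_e)
        K[:, :, j] = f.reshape(E, 24).imag / _CS_H
    return 0.5 * (K + K.swapaxes(1, 2))


def assemble_tangent(
    mesh: HexMesh, pre: Precomputed, u: np.ndarray,
    C_e: np.ndarray, D_e: np.ndarray,
) -> sparse.csr_matrix:
    """Assembled global tangent (3N x 3N, CSR)."""
    K_e = element_tangents(mesh, pre, u, C_e, D_e)
    rows = np.repeat(pre.dof_idx, 24, axis=1).ravel()
    cols = np.tile(pre.dof_idx, (1, 24)).ravel()
    n = 3 * mesh.n_nodes
    return sparse.coo_matrix(
        (K_e.ravel(), (rows, cols)), shape=(n, n)).tocsr()
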