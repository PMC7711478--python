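"""Constitutive law and semi-analytic layered uniaxial solver.

Kinematics follow the multiplicative growth decomposition F = F* . G,
where G is the growth tensor and F* the elastic deformation gradient.
This package models only the elastic response (G = I), so F = F*; the
decomposition is kept in :class:`DeformationState` so the bookkeeping is
explicit.

Constitutive model (compressible neo-Hookean):

    W(F)     = C (I1_bar - 3) + (1/D) [ (J^2 - 1)/2 - ln J ]
    I1_bar   = J^(-2/3) tr(F^T F),   J = det F
    sigma(F) = (2C/J) dev(B_bar) + (1/D) (J - 1/J) I
    B_bar    = J^(-2/3) F F^T

The Cauchy stress is the push-forward (1/J) F (dW/dE) F^T of the second
Piola-Kirchhoff stress; the closed form above is what the package uses,
and it is cross-checked against a finite-difference dW/dE in the test
suite. D = 0 encodes exact incompressibility: the volumetric term is
dropped and J must equal 1.

The semi-analytic uniaxial solver treats each wall layer as a
traction-free bar in parallel (iso-strain): every layer carries the
common axial stretch, its lateral stretch solves sigma_lateral = 0, and
the axial force is the sum of nominal stress times undeformed annular
area. It is the reference oracle for the FEM, which additionally
resolves interlayer radial interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidParameterError, InvertedElementError, SolverFailureError
from .geometry import LAYER_NAMES, IntestineModelSpec
from .materials import LayerMaterial

_EYE = np.eye(3)

#: |J - 1| tolerance when D = 0 (exact incompressibility).
_INCOMPRESSIBLE_J_TOL = 1e-8


@dataclass(frozen=True)
class DeformationState:
    """Kinematic/stress state at a material point.

    F_total = F_elastic . G_growth; with G = I (no growth modelled) the two
    gradients coincide. E_lagrange = (F^T F - I)/2 uses the elastic
    gradient, as do J, I1_bar and the Cauchy stress.
    """

    F_total: np.ndarray
    F_elastic: np.ndarray
    G_growth: np.ndarray
    J: float
    E_lagrange: np.ndarray
    I1_bar: float
    cauchy: np.ndarray | None = None

    @classmethod
    def from_deformation_gradient(
        cls,
        F: np.ndarray,
        G: np.ndarray | None = None,
        material: LayerMaterial | None = None,
    ) -> "DeformationState":
        F = np.asarray(F, dtype=float)
        G_growth = _EYE if G is None else np.asarray(G, dtype=float)
        F_elastic = F @ np.linalg.inv(G_growth)
        J = float(np.linalg.det(F_elastic))
        if J <= 0:
            raise InvertedElementError(f"det F = {J} <= 0")
        E = 0.5 * (F_elastic.T @ F_elastic - _EYE)
        I1_bar = float(J ** (-2.0 / 3.0) * np.trace(F_elastic.T @ F_elastic))
        sigma = None
        if material is not None:
            sigma = cauchy_stress(F_elastic, material.C, material.D)
        return cls(F_total=F, F_elastic=F_elastic, G_growth=G_growth,
                   J=J, E_lagrange=E, I1_bar=I1_bar, cauchy=sigma)


def _check_F(F: np.ndarray) -> tuple[np.ndarray, float]:
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise InvalidParameterError(f"F must be 3x3, got shape {F.shape}")
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvertedElementError(f"det F = {J} <= 0")
    return F, J


def strain_energy(F: np.ndarray, C: float, D: float) -> float:
    """Neo-Hookean strain-energy density W(F) in MPa (= mJ/mm^3)."""
    F, J = _check_F(F)
    I1_bar = J ** (-2.0 / 3.0) * float(np.einsum("ij,ij->", F, F))
    W = C * (I1_bar - 3.0)
    if D == 0.0:
        if abs(J - 1.0) > _INCOMPRESSIBLE_J_TOL:
            raise InvalidParameterError(
                f"D = 0 (incompressible) requires J = 1, got J = {J}")
        return float(W)
    W += (1.0 / D) * (0.5 * (J * J - 1.0) - np.log(J))
    return float(W)


def cauchy_stress(F: np.ndarray, C: float, D: float) -> np.ndarray:
    """Closed-form Cauchy stress sigma(F) in MPa.

    sigma = (2C/J) dev(B_bar) + (1/D)(J - 1/J) I. For D = 0 only the
    deviatoric part is returned (J must be 1; the pressure is then
    indeterminate and must come from boundary conditions).
    """
    F, J = _check_F(F)
    B_bar = J ** (-2.0 / 3.0) * (F @ F.T)
    dev = B_bar - (np.trace(B_bar) / 3.0) * _EYE
    sigma = (2.0 * C / J) * dev
    if D == 0.0:
        if abs(J - 1.0) > _INCOMPRESSIBLE_J_TOL:
            raise InvalidParameterError(
                f"D = 0 (incompressible) requires J = 1, got J = {J}")
        return sigma
    return sigma + (1.0 / D) * (J - 1.0 / J) * _EYE


def second_pk_finite_difference(
    F: np.ndarray, C: float, D: float, h: float = 1e-6
) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = dW/dE by central differences.

    Independent oracle used to validate :func:`cauchy_stress` through
    sigma = (1/J) F S F^T. W is evaluated as a function of the right
    Cauchy-Green tensor (C_right = I + 2E); symmetric perturbations of E
    keep the physics frame-indifferent.
    """
    F, _ = _check_F(F)
    C_right = F.T @ F

    def W_of_Cright(Cr: np.ndarray) -> float:
        J2 = float(np.linalg.det(Cr))
        J = np.sqrt(J2)
        I1_bar = J2 ** (-1.0 / 3.0) * float(np.trace(Cr))
        W = C * (I1_bar - 3.0)
        if D != 0.0:
            W += (1.0 / D) * (0.5 * (J2 - 1.0) - np.log(J))
        return W

    S = np.zeros((3, 3))
    for i in range(3):
        for j in range(i, 3):
            dE = np.zeros((3, 3))
            dE[i, j] += h
            if i != j:
                dE[j, i] += h  # keep the perturbation symmetric
            Wp = W_of_Cright(C_right + 2.0 * dE)
            Wm = W_of_Cright(C_right - 2.0 * dE)
            # dW = S : dE summed over both (i,j) and (j,i) entries
            d = (Wp - Wm) / (4.0 * h) if i != j else (Wp - Wm) / (2.0 * h)
            S[i, j] = S[j, i] = d
    return S


def cauchy_stress_finite_difference(
    F: np.ndarray, C: float, D: float, h: float = 1e-6
) -> np.ndarray:
    """Cauchy stress via the finite-difference dW/dE pushed forward."""
    F, J = _check_F(F)
    S = second_pk_finite_difference(F, C, D, h=h)
    return (F @ S @ F.T) / J


@dataclass(frozen=True)
class UniaxialLayerState:
    """Uniaxial state of one layer at a given axial stretch."""

    lambda_z: float
    lambda_r: float
    J: float
    sigma_zz: float  # Cauchy axial stress, MPa
    sigma_lateral: float  # residual lateral Cauchy stress (solver check)
    nominal_zz: float  # first Piola axial stress Pzz = J sigma_zz / lambda_z


def uniaxial_layer_response(
    lambda_z: float,
    material: LayerMaterial,
    bracket: tuple[float, float] = (0.3, 1.5),
    tol: float = 1e-12,
) -> UniaxialLayerState:
    """Uniaxial stress state: solve sigma_lateral(lambda_r; lambda_z) = 0.

    F = diag(lambda_r, lambda_r, lambda_z) with traction-free lateral
    faces. For D = 0 the solution is the closed-form incompressible one
    (lambda_r = lambda_z^(-1/2), sigma_zz = 2C (lz^2 - 1/lz)).
    """
    if lambda_z <= 0:
        raise InvalidParameterError(f"lambda_z must be > 0, got {lambda_z}")
    C, D = material.C, material.D

    if D == 0.0:
        lam_r = lambda_z ** -0.5
        sigma_zz = 2.0 * C * (lambda_z ** 2 - 1.0 / lambda_z)
        return UniaxialLayerState(
            lambda_z=lambda_z, lambda_r=lam_r, J=1.0, sigma_zz=sigma_zz,
            sigma_lateral=0.0, nominal_zz=sigma_zz / lambda_z)

    def lateral_stress(lam_r: float) -> float:
        F = np.diag([lam_r, lam_r, lambda_z])
        return cauchy_stress(F, C, D)[0, 0]

    lo, hi = bracket
    f_lo, f_hi = lateral_stress(lo), lateral_stress(hi)
    if f_lo * f_hi > 0:
        raise SolverFailureError(
            "lateral-stress root not bracketed",
            diagnostics={"bracket": bracket, "f_lo": f_lo, "f_hi": f_hi,
                         "lambda_z": lambda_z})
    lam_r = brentq(lateral_stress, lo, hi, xtol=1e-14, rtol=8.9e-16)
    F = np.diag([lam_r, lam_r, lambda_z])
    sigma = cauchy_stress(F, C, D)
    J = lam_r * lam_r * lambda_z
    if abs(sigma[0, 0]) > max(tol, 1e-10):
        raise SolverFailureError(
            "lateral stress not driven to zero",
            diagnostics={"sigma_lateral": sigma[0, 0]})
    return UniaxialLayerState(
        lambda_z=lambda_z, lambda_r=lam_r, J=J,
        sigma_zz=float(sigma[2, 2]), sigma_lateral=float(sigma[0, 0]),
        nominal_zz=float(sigma[2, 2]) * J / lambda_z)


def layered_doubling_force(
    spec: IntestineModelSpec,
    materials: Mapping[str, LayerMaterial],
    stretch: float = 2.0,
) -> float:
    """Axial force (N) to stretch the layered segment to ``stretch``.

    Iso-strain layer coupling: all wall layers share the axial stretch
    and each is laterally traction-free; radial interlayer pressure is
    neglected (the FEM resolves it, and agrees to a few parts in a
    thousand at nu = 0.49). Force = sum over layers of nominal axial
    stress times undeformed annular area. The mesentery, if configured,
    is not part of the axial load path in this reduction.
    """
    areas = spec.layer_areas_mm2()
    force = 0.0
    for name, area in zip(LAYER_NAMES, areas):
        state = uniaxial_layer_response(stretch, materials[name])
        force += state.nominal_zz * area
    return float(force)


def layered_force_breakdown(
    spec: IntestineModelSpec,
    materials: Mapping[str, LayerMaterial],
    stretch: float = 2.0,
) -> dict[str, float]:
    """Per-layer contribution (N) to the semi-analytic doubling force."""
    areas = spec.layer_areas_mm2()
    return {
        name: uniaxial_layer_response(stretch, materials[name]).nominal_zz * area
        for name, area in zip(LAYER_NAMES, areas)
    }
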