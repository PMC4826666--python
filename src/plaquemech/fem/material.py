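"""Neo-Hookean constitutive relations in plane strain.

The tissue model is the incompressible Neo-Hookean solid with strain energy
W = C (I1 - 3), C the shear modulus (so the small-strain shear modulus is
mu = 2C) and I1 the first invariant of the left Cauchy-Green tensor.  In
plane strain the out-of-plane stretch is 1, so I1 = tr(F2^T F2) + 1 with F2
the in-plane deformation gradient.  The solver enforces (near-)
incompressibility either by a condensed mixed pressure field or by a
volumetric penalty; this module provides the first Piola-Kirchhoff stress
and its exact tangent for the compressible parent model

    W(F) = (mu/2)(I1 - 3) - mu ln J + (lam/2)(ln J)^2,

which reduces to C(I1 - 3) on the incompressible manifold J = 1.
All moduli in kPa, stresses in kPa.
"""

from __future__ import annotations

import numpy as np

__all__ = ["strain_energy_density", "pk1_and_tangent", "pressure_stress_tangent"]

_EYE2 = np.eye(2)


def strain_energy_density(C: float, deformation_gradient: np.ndarray) -> float:
    """Incompressible Neo-Hookean strain energy W = C (I1 - 3), kPa.

    ``deformation_gradient`` is the 2x2 in-plane tensor; the out-of-plane
    stretch is 1 (plane strain), and the incompressibility constraint itself
    is handled by the solver's mixed/penalty formulation.  Raises for a
    non-positive Jacobian.
    """
    F = np.asarray(deformation_gradient, float)
    if F.shape != (2, 2):
        raise ValueError("deformation gradient must be 2x2 (in-plane)")
    J = F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0]
    if J <= 0:
        raise ValueError("non-positive Jacobian: element inversion")
    i1 = float(np.sum(F * F)) + 1.0
    return C * (i1 - 3.0)


def _inv_2x2(F):
    """Vectorized 2x2 inverse and determinant; F shape (..., 2, 2)."""
    J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    Finv = np.empty_like(F)
    Finv[..., 0, 0] = F[..., 1, 1]
    Finv[..., 0, 1] = -F[..., 0, 1]
    Finv[..., 1, 0] = -F[..., 1, 0]
    Finv[..., 1, 1] = F[..., 0, 0]
    Finv /= J[..., None, None]
    return Finv, J


def pk1_and_tangent(F, mu, lam):
    """PK1 stress P and material tangent A = dP/dF for the penalty model.

    F: (..., 2, 2); mu, lam broadcastable to F[..., 0, 0].
    Returns (P (..., 2, 2), A (..., 2, 2, 2, 2), J (...)).

        P = mu F + (lam ln J - mu) F^{-T}
        A_iJkL = mu d_ik d_JL - (lam ln J - mu) FiT_iL FiT_kJ
                 + lam FiT_iJ FiT_kL
    """
    F = np.asarray(F, float)
    Finv, J = _inv_2x2(F)
    if np.any(J <= 0):
        raise FloatingPointError("non-positive Jacobian during assembly")
    FiT = np.swapaxes(Finv, -1, -2)
    lnJ = np.log(J)
    mu = np.asarray(mu, float)[..., None, None]
    lam_ = np.asarray(lam, float)[..., None, None]
    coef = lam_ * lnJ[..., None, None] - mu
    P = mu * F + coef * FiT

    dd = np.einsum("ik,JL->iJkL", _EYE2, _EYE2)
    A = (mu[..., None, None] * dd
         - coef[..., None, None] * np.einsum("...iL,...kJ->...iJkL", FiT, FiT)
         + lam_[..., None, None] * np.einsum("...iJ,...kL->...iJkL", FiT, FiT))
    return P, A, J


def pressure_stress_tangent(F, mu, p):
    """PK1 stress and tangent for the mixed formulation at given element
    pressure p (kPa):

        P = mu (F - F^{-T}) + p J F^{-T}

    The tangent here holds p fixed; the condensation rank-one term is added
    by the solver.  Returns (P, A, J, J*F^{-T}).
    """
    F = np.asarray(F, float)
    Finv, J = _inv_2x2(F)
    if np.any(J <= 0):
        raise FloatingPointError("non-positive Jacobian during assembly")
    FiT = np.swapaxes(Finv, -1, -2)
    mu = np.asarray(mu, float)[..., None, None]
    pJ = (np.asarray(p, float) * J)[..., None, None]
    P = mu * (F - FiT) + pJ * FiT

    dd = np.einsum("ik,JL->iJkL", _EYE2, _EYE2)
    A = (mu[..., None, None] * dd
         - (pJ - mu)[..., None, None] * np.einsum("...iL,...kJ->...iJkL", FiT, FiT)
         + pJ[..., None, None] * np.einsum("...iJ,...kL->...iJkL", FiT, FiT))
    return P, A, J, J[..., None, None] * FiT
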