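"""Closed-form/1D-quadrature oracle: incompressible Neo-Hookean tube.

Plane-strain inflation of a homogeneous thick-walled cylinder with
W = C (I1 - 3).  Incompressibility fixes the kinematics,

    r(R)^2 = R^2 + a^2 - A^2,   lambda_theta = r / R,

and radial equilibrium integrates to the pressure-expansion relation

    P(a) = int_a^b (sigma_tt - sigma_rr) / r dr,
    sigma_tt - sigma_rr = 2 C (lambda^2 - lambda^-2),

with A, B the reference inner/outer radii and a, b their deformed values.
The deformed inner radius for a given pressure follows by root finding.
This is an independent verification oracle for the 2D FE solver.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = ["tube_pressure", "analytic_tube_inflation", "linear_tube_expansion"]


def tube_pressure(C: float, inner_radius: float, outer_radius: float,
                  deformed_inner: float) -> float:
    """Luminal pressure (kPa) producing deformed inner radius ``a``."""
    A, B, a = inner_radius, outer_radius, deformed_inner
    b = np.sqrt(B * B + a * a - A * A)

    def integrand(r):
        R2 = r * r - a * a + A * A
        lam2 = r * r / R2
        return 2.0 * C * (lam2 - 1.0 / lam2) / r

    val, _ = quad(integrand, a, b, limit=200)
    return val


def analytic_tube_inflation(C: float, inner_radius: float, outer_radius: float,
                            P: float) -> float:
    """Deformed inner radius (mm) of the incompressible Neo-Hookean tube.

    Raises ValueError if no root exists in the physical range (pressure
    beyond the quasi-static expansion branch).
    """
    if not 0 < inner_radius < outer_radius:
        raise ValueError("require 0 < inner_radius < outer_radius")
    if C <= 0:
        raise ValueError("shear modulus must be positive")
    A = inner_radius
    if P == 0:
        return A

    def g(a):
        return tube_pressure(C, inner_radius, outer_radius, a) - P

    lo = A if P > 0 else 0.2 * A
    hi = A
    if P > 0:
        step = 0.5 * A
        for _ in range(60):
            hi = hi + step
            if g(hi) > 0:
                return brentq(g, lo, hi, xtol=1e-12, rtol=1e-14)
        raise ValueError("no root in physical range: pressure too high for this tube")
    if g(lo) > 0:
        raise ValueError("no root in physical range")
    return brentq(g, lo, hi, xtol=1e-12, rtol=1e-14)


def linear_tube_expansion(C: float, inner_radius: float, outer_radius: float,
                          P: float) -> float:
    """Small-load limit: Lame thick-wall solution for an incompressible
    linear-elastic tube (shear modulus mu = 2C, plane strain, nu = 1/2):

        u(A) = P A B^2 / (2 mu (B^2 - A^2))
    """
    A, B = inner_radius, outer_radius
    mu = 2.0 * C
    return P * A * B * B / (2.0 * mu * (B * B - A * A))
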