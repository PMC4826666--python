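"""Newton-Raphson solution of the inflated plaque cross-section.

Total-Lagrangian quadratic triangles; tissue regions use either a condensed
mixed formulation (element-wise pressure, perturbed-Lagrangian bulk modulus
kappa = kappa_factor * C) or a near-incompressible volumetric penalty with
the same kappa; the buffer ring is compressible (Poisson ratio 0).  Pressure
is a follower load on the deformed lumen boundary; the buffer's outer rim is
clamped.  Load stepping bisects automatically on divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from plaquemech.errors import ConvergenceError
from plaquemech.fem.material import pk1_and_tangent, pressure_stress_tangent
from plaquemech.fem.mesh import Mesh
from plaquemech.phantom import MaterialMap
from plaquemech.units import mmhg_to_kpa

__all__ = ["PressureProtocol", "FESolution", "SolverOptions", "solve_inflation",
           "deformed_tissue_area"]

# 3-point interior quadrature on the reference triangle (degree 2)
_QP = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_QW = np.full(3, 1 / 6)

# 3-point Gauss on [0, 1] for boundary edges
_EQ = np.array([0.5 - 0.5 * np.sqrt(0.6), 0.5, 0.5 + 0.5 * np.sqrt(0.6)])
_EW = np.array([5 / 18, 8 / 18, 5 / 18])

_ZCROSS = np.array([[0.0, -1.0], [1.0, 0.0]])  # (z x v)_i = Z_ij v_j


def _grad_ref(xi, eta):
    """P2 shape-function gradients on the reference triangle, (6, 2)."""
    l1 = 1.0 - xi - eta
    return np.array([
        [1 - 4 * l1, 1 - 4 * l1],
        [4 * xi - 1, 0.0],
        [0.0, 4 * eta - 1],
        [4 * (l1 - xi), -4 * xi],
        [4 * eta, 4 * xi],
        [-4 * eta, 4 * (l1 - eta)],
    ])


def _edge_shapes(xi):
    """Quadratic edge shape functions (start, mid, end) and derivatives."""
    n = np.array([(1 - xi) * (1 - 2 * xi), 4 * xi * (1 - xi), xi * (2 * xi - 1)])
    dn = np.array([4 * xi - 3, 4 - 8 * xi, 4 * xi - 1])
    return n, dn


@dataclass
class PressureProtocol:
    """Ordered luminal pressure levels in mmHg (strictly increasing, >= 0)."""

    levels_mmhg: np.ndarray

    def __post_init__(self):
        self.levels_mmhg = np.asarray(self.levels_mmhg, float).reshape(-1)
        if len(self.levels_mmhg) == 0:
            raise ValueError("protocol needs at least one pressure level")
        if self.levels_mmhg[0] < 0 or np.any(np.diff(self.levels_mmhg) <= 0):
            raise ValueError("pressure levels must be non-negative and strictly increasing")

    @property
    def levels_kpa(self) -> np.ndarray:
        return mmhg_to_kpa(self.levels_mmhg)

    @classmethod
    def default(cls) -> "PressureProtocol":
        """Inflation-test protocol landmarks: 10, 80, 100, 120 mmHg."""
        return cls(np.array([10.0, 80.0, 100.0, 120.0]))


@dataclass
class FESolution:
    """Converged state at one pressure level."""

    pressure_kpa: float
    nodal_displacements: np.ndarray     # (n_nodes, 2), mm
    converged: bool
    newton_iterations: int
    residual_norm: float = np.nan


@dataclass
class SolverOptions:
    formulation: str = "mixed"          # "mixed" or "penalty"
    newton_tol: float = 1e-8            # relative residual
    max_newton: int = 25
    max_bisect: int = 8
    kappa_factor: float = 1e4           # bulk modulus = kappa_factor * C (tissue)
    max_total_newton: int = 600         # iteration budget per load target


class _Diverged(Exception):
    pass


class FEOperator:
    """Precomputed assembly operator for one mesh + material map."""

    def __init__(self, mesh: Mesh, materials: MaterialMap,
                 options: SolverOptions | None = None):
        self.mesh = mesh
        self.materials = materials
        self.opts = options or SolverOptions()
        if self.opts.formulation not in ("mixed", "penalty"):
            raise ValueError("formulation must be 'mixed' or 'penalty'")

        x = mesh.nodes[mesh.elements[:, :3]]                     # (nel, 3, 2)
        jac = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]], axis=-1)
        self.detJ = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
        jinv = np.linalg.inv(jac)                                # (nel, 2, 2)
        gref = np.stack([_grad_ref(*q) for q in _QP])            # (nqp, 6, 2)
        self.gradN = np.einsum("qaj,eji->eqai", gref, jinv)      # (nel, nqp, 6, 2)
        self.area = 0.5 * self.detJ

        C_el = np.array([materials.modulus(r) for r in mesh.region])
        self.mu = 2.0 * C_el
        self.is_buffer = mesh.region_mask("buffer")
        self.kappa = np.where(self.is_buffer, 0.0, self.opts.kappa_factor * C_el)
        if self.opts.formulation == "mixed":
            self.mixed_mask = ~self.is_buffer
        else:
            self.mixed_mask = np.zeros(mesh.n_elements, bool)

        dofs = np.empty((mesh.n_elements, 12), dtype=np.int64)
        dofs[:, 0::2] = 2 * mesh.elements
        dofs[:, 1::2] = 2 * mesh.elements + 1
        self.dofs = dofs
        self._rows = np.repeat(dofs, 12, axis=1).ravel()
        self._cols = np.tile(dofs, (1, 12)).ravel()

        edofs = np.empty((len(mesh.lumen_edges), 6), dtype=np.int64)
        edofs[:, 0::2] = 2 * mesh.lumen_edges
        edofs[:, 1::2] = 2 * mesh.lumen_edges + 1
        self._edofs = edofs
        self._erows = np.repeat(edofs, 6, axis=1).ravel()
        self._ecols = np.tile(edofs, (1, 6)).ravel()
        # edge integral of N_a * N'_b (3x3), constant in the reference edge
        m1 = np.zeros((3, 3))
        for xi, w in zip(_EQ, _EW):
            n, dn = _edge_shapes(xi)
            m1 += w * np.outer(n, dn)
        self._edge_m1 = m1

        free = np.ones(2 * mesh.n_nodes, bool)
        free[2 * mesh.fixed_nodes] = False
        free[2 * mesh.fixed_nodes + 1] = False
        self.free = free
        self.ndof = 2 * mesh.n_nodes

    # -- kinematics -------------------------------------------------------
    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        """F at every quadrature point, (nel, nqp, 2, 2)."""
        u_el = u[self.mesh.elements]                             # (nel, 6, 2)
        F = np.einsum("eai,eqaJ->eqiJ", u_el, self.gradN)
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        return F

    # -- assembly ---------------------------------------------------------
    def _internal(self, u):
        F = self.deformation_gradients(u)
        mu_q = np.broadcast_to(self.mu[:, None], F.shape[:2])
        P = np.empty_like(F)
        A = np.empty(F.shape[:2] + (2, 2, 2, 2))
        Ke_extra = None

        pen = ~self.mixed_mask
        if pen.any():
            lam_q = np.broadcast_to(self.kappa[pen, None], F[pen].shape[:2])
            P[pen], A[pen], _ = pk1_and_tangent(F[pen], mu_q[pen], lam_q)
        if self.mixed_mask.any():
            m = self.mixed_mask
            Fm = F[m]
            Jq = Fm[..., 0, 0] * Fm[..., 1, 1] - Fm[..., 0, 1] * Fm[..., 1, 0]
            if np.any(Jq <= 0):
                raise FloatingPointError("non-positive Jacobian during assembly")
            wdet = (_QW[None, :] * self.detJ[m, None])
            vol0 = wdet.sum(axis=1)
            p_el = self.kappa[m] / vol0 * np.sum(wdet * (Jq - 1.0), axis=1)
            Pm, Am, _, JFiT = pressure_stress_tangent(
                Fm, np.broadcast_to(self.mu[m, None], Fm.shape[:2]),
                np.broadcast_to(p_el[:, None], Fm.shape[:2]))
            P[m], A[m] = Pm, Am
            # condensation rank-one: g_(a,i) = int J F^{-T}_iJ dN_a/dX_J
            g = np.einsum("q,e,eqiJ,eqaJ->eai", _QW, self.detJ[m], JFiT,
                          self.gradN[m], optimize=True).reshape(len(p_el), 12)
            Ke_extra = (m, (self.kappa[m] / vol0)[:, None, None]
                        * g[:, :, None] * g[:, None, :])

        wdet_all = _QW[None, :] * self.detJ[:, None]
        f_el = np.einsum("eq,eqiJ,eqaJ->eai", wdet_all, P, self.gradN, optimize=True)
        f_int = np.zeros(self.ndof)
        np.add.at(f_int, self.dofs.ravel(), f_el.reshape(-1))
        # element tangents: K_(ai)(bk) = sum_q w detJ A_iJkL gradN_aJ gradN_bL
        Ke = np.einsum("eq,eqiJkL,eqaJ,eqbL->eaibk", wdet_all, A,
                       self.gradN, self.gradN, optimize=True).reshape(self.mesh.n_elements, 12, 12)
        if Ke_extra is not None:
            m, extra = Ke_extra
            Ke[m] += extra
        return f_int, Ke

    def _external(self, u, pressure):
        """Follower pressure on the lumen boundary: force and load stiffness."""
        f_ext = np.zeros(self.ndof)
        edges = self.mesh.lumen_edges
        xcur = self.mesh.nodes + u                               # (n_nodes, 2)
        xe = xcur[edges]                                         # (ne, 3, 2)
        fe = np.zeros((len(edges), 3, 2))
        for xi, w in zip(_EQ, _EW):
            n, dn = _edge_shapes(xi)
            dx = np.einsum("b,ebi->ei", dn, xe)                  # tangent
            zxt = dx @ _ZCROSS.T                                 # z x tangent
            fe += -pressure * w * n[None, :, None] * zxt[:, None, :]
        np.add.at(f_ext, self._edofs.ravel(), fe.reshape(-1))
        # load stiffness dF/du, constant blocks scaled by pressure
        kb = -pressure * np.einsum("ab,ik->aibk", self._edge_m1, _ZCROSS)
        kb = kb.reshape(6, 6)
        kvals = np.broadcast_to(kb, (len(edges), 6, 6)).ravel()
        return f_ext, kvals

    def residual_and_tangent(self, u, pressure):
        f_int, Ke = self._internal(u)
        f_ext, kvals_ext = self._external(u, pressure)
        R = f_int - f_ext
        rows = np.concatenate([self._rows, self._erows])
        cols = np.concatenate([self._cols, self._ecols])
        vals = np.concatenate([Ke.ravel(), -kvals_ext])
        K = sp.coo_matrix((vals, (rows, cols)), shape=(self.ndof, self.ndof)).tocsr()
        return R, K, f_ext

    # -- Newton -----------------------------------------------------------
    def newton(self, u0, pressure):
        """Newton iteration at fixed pressure; raises _Diverged on failure."""
        u = u0.copy()
        free = self.free
        ref = None
        for it in range(self.opts.max_newton):
            try:
                R, K, f_ext = self.residual_and_tangent(u.reshape(-1, 2), pressure)
            except FloatingPointError as exc:
                raise _Diverged(str(exc)) from exc
            Rf = R[free]
            rn = np.linalg.norm(Rf)
            if not np.isfinite(rn):
                raise _Diverged("non-finite residual")
            if ref is None:
                ref = max(np.linalg.norm(f_ext[free]), 1e-12)
            if rn <= self.opts.newton_tol * ref:
                return u, it, rn
            Kff = K[free][:, free]
            du = spla.spsolve(Kff.tocsc(), -Rf)
            if not np.all(np.isfinite(du)):
                raise _Diverged("singular tangent")
            u.reshape(-1)[np.nonzero(free)[0]] += du
        raise _Diverged(f"no convergence in {self.opts.max_newton} iterations")

    def try_newton(self, u0, pressure):
        """Newton at fixed pressure; (u, iters, rnorm), or None on
        divergence."""
        try:
            return self.newton(u0, pressure)
        except _Diverged:
            return None

    def continue_to(self, u_start, p_start, p_target, on_state=None):
        """Advance from (u_start, p_start) to p_target with automatic load
        bisection.  ``on_state(p, u)`` is called at every converged
        intermediate load.  Raises :class:`ConvergenceError` when the
        bisection depth or the iteration budget is exhausted."""
        u, p = u_start, p_start
        total = 0
        rn = np.nan
        first = True
        while first or p < p_target - 1e-14:
            first = False
            p_try = p_target
            depth = 0
            while True:
                try:
                    u_new, its, rn = self.newton(u, p_try)
                    total += its + 1
                    break
                except _Diverged as exc:
                    total += self.opts.max_newton
                    depth += 1
                    if depth > self.opts.max_bisect:
                        raise ConvergenceError(
                            f"no convergence at P = {p_try:.4g} kPa after "
                            f"{self.opts.max_bisect} bisections: {exc}") from exc
                    if total > self.opts.max_total_newton:
                        raise ConvergenceError(
                            f"iteration budget exhausted at P = {p_try:.4g} kPa")
                    p_try = 0.5 * (p + p_try)
            u, p = u_new, p_try
            if on_state is not None:
                on_state(p, u)
            if total > self.opts.max_total_newton and p < p_target - 1e-14:
                raise ConvergenceError(
                    f"iteration budget exhausted at P = {p:.4g} kPa")
        return u, total, rn


def solve_inflation(mesh: Mesh, materials: MaterialMap,
                    protocol: PressureProtocol,
                    options: SolverOptions | None = None,
                    warm_start: list[np.ndarray] | None = None) -> list[FESolution]:
    """Solve the inflation at every protocol level.

    Returns one converged :class:`FESolution` per level (pressures in kPa).
    ``warm_start`` may supply initial displacement guesses per level (e.g.
    the converged states of a neighboring material candidate); on failure
    the solver falls back to load continuation from the previous level.
    Raises :class:`ConvergenceError` when bisection is exhausted.
    """
    op = FEOperator(mesh, materials, options)
    levels = protocol.levels_kpa
    out: list[FESolution] = []
    u_prev = np.zeros((mesh.n_nodes, 2))
    p_prev = 0.0
    for i, p in enumerate(levels):
        guess = None
        if warm_start is not None and i < len(warm_start) and warm_start[i] is not None:
            guess = np.asarray(warm_start[i], float)
        if guess is not None:
            try:
                u, its, rn = op.newton(guess, p)
            except _Diverged:
                u, its, rn = op.continue_to(u_prev, p_prev, p)
        else:
            u, its, rn = op.continue_to(u_prev, p_prev, p)
        out.append(FESolution(float(p), u.copy(), True, its, rn))
        u_prev, p_prev = u, p
    return out


def deformed_tissue_area(mesh: Mesh, u: np.ndarray,
                         regions=("intima", "wall", "calcium")) -> float:
    """Deformed area (mm²) of the given regions: integral of det F."""
    op_mask = mesh.region_mask(*regions)
    x = mesh.nodes[mesh.elements[:, :3]]
    jac = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]], axis=-1)
    detJ = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
    jinv = np.linalg.inv(jac)
    gref = np.stack([_grad_ref(*q) for q in _QP])
    gradN = np.einsum("qaj,eji->eqai", gref, jinv)
    u_el = np.asarray(u)[mesh.elements]
    F = np.einsum("eai,eqaJ->eqiJ", u_el, gradN)
    F[..., 0, 0] += 1.0
    F[..., 1, 1] += 1.0
    J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    wdet = _QW[None, :] * detJ[:, None]
    return float(np.sum((wdet * J)[op_mask]))
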