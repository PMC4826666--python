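"""Inverse estimation of wall and intima shear moduli.

Measured and computed axial displacements are averaged over a measurement
grid of 100 µm square cells forming a column through the plaque thickness
in the central (axial) band of the image — the region where the ultrasound
beam direction coincides with the radial direction.  For each incremental
pressure step the objective

    F = sum_j (u_j_comp - u_j_meas)^2        [mm^2]

is minimized by exhaustive grid search of (C_wall, C_intima) over
[1, 400] kPa, and the goodness of fit is reported as

    du_rel = (sqrt(F) / n) / u_mean_meas * 100%

with u_mean_meas the mean absolute measured cell displacement of the step.
Young's moduli follow from incompressibility as E = 6 C.  Only the axial
displacement component enters the objective; lateral estimates are far
noisier and are kept for reporting only.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box

from plaquemech import _geom
from plaquemech.errors import ConvergenceError
from plaquemech.phantom import MaterialMap, PlaqueGeometry
from plaquemech.fem import FieldInterpolator, SolverOptions
from plaquemech.tracking import DisplacementMap
from plaquemech.units import mmhg_to_kpa

log = logging.getLogger("plaquemech.inverse")

__all__ = [
    "MeasurementGrid", "StepDefinition", "StiffnessEstimate", "LatticeSpec",
    "default_steps", "build_measurement_grid", "average_on_grid",
    "objective_F", "relative_difference", "young_from_shear",
    "tissue_compression", "grid_search", "FEForward", "intima_sensitivity",
]


@dataclass
class MeasurementGrid:
    """Square cells (side ``cell_size_um``) through the plaque thickness."""

    centers: np.ndarray          # (n, 2) mm
    cell_size_um: float

    @property
    def n(self) -> int:
        return len(self.centers)

    @property
    def half_mm(self) -> float:
        return 0.5 * self.cell_size_um * 1e-3

    def cell_polygons(self):
        h = self.half_mm
        return [box(cx - h, cy - h, cx + h, cy + h) for cx, cy in self.centers]


@dataclass(frozen=True)
class StepDefinition:
    """One incremental pressure step of the inflation protocol."""

    step_id: int
    p_from_mmhg: float
    p_to_mmhg: float

    def __post_init__(self):
        if self.p_to_mmhg <= self.p_from_mmhg:
            raise ValueError("step must increase pressure")


def default_steps() -> tuple:
    """The three incremental steps: 10-80, 80-100, 100-120 mmHg."""
    return (StepDefinition(1, 10.0, 80.0),
            StepDefinition(2, 80.0, 100.0),
            StepDefinition(3, 100.0, 120.0))


@dataclass
class StiffnessEstimate:
    """Grid-search result for one pressure step."""

    step: StepDefinition
    C_wall: float
    C_intima: float
    F_mm2: float
    delta_u_rel_pct: float
    n_cells: int

    @property
    def E_wall(self) -> float:
        return young_from_shear(self.C_wall)

    @property
    def E_intima(self) -> float:
        return young_from_shear(self.C_intima)


def build_measurement_grid(geometry: PlaqueGeometry,
                           band_halfwidth: float = 0.25,
                           cell_size_um: float = 100.0) -> MeasurementGrid:
    """Build the measurement grid: a vertical column of square cells.

    Cells of side ``cell_size_um`` tile the axial (vertical) line through
    the lumen center, clipped to tissue between the lumen and the outer
    contour (above and below the lumen); every cell must fit inside the
    lateral band |x - x_center| <= ``band_halfwidth``.  Raises when the
    band misses the plaque or no cell fits.
    """
    cs = cell_size_um * 1e-3
    if cs / 2 > band_halfwidth:
        raise ValueError("cells do not fit in the requested band")
    cx, cy = geometry.center
    ring = (_geom.to_polygon(geometry.outer_contour)
            .difference(_geom.to_polygon(geometry.lumen_contour)))
    minx, miny, maxx, maxy = ring.bounds
    if not (minx <= cx <= maxx):
        raise ValueError("measurement band lies outside the vessel")
    ys = np.arange(miny + cs / 2, maxy - cs / 2 + 1e-12, cs)
    centers = []
    for y in ys:
        cell = box(cx - cs / 2, y - cs / 2, cx + cs / 2, y + cs / 2)
        if ring.buffer(1e-9).contains(cell):
            centers.append((cx, y))
    if not centers:
        raise ValueError("no measurement cell fits inside the tissue")
    return MeasurementGrid(np.array(centers), cell_size_um)


def average_on_grid(fld, grid: MeasurementGrid,
                    allow_partial: bool = False) -> np.ndarray:
    """Per-cell mean axial displacement (mm).

    ``fld`` is either a :class:`DisplacementMap` (measured: arithmetic mean
    of the map samples falling in each cell) or a callable mapping (m, 2)
    positions (mm) to (m, 2) displacement vectors (computed: fixed 4 x 4
    quadrature of interpolated values).  Cells without any valid sample
    raise unless ``allow_partial``, in which case they yield NaN.
    """
    h = grid.half_mm
    out = np.full(grid.n, np.nan)
    if isinstance(fld, DisplacementMap):
        y, x = fld.node_positions_mm()
        X, Y = np.meshgrid(x, y)
        vals = fld.axial_um * 1e-3
        pts = np.column_stack([X.ravel(), Y.ravel(), vals.ravel()])
        for k, (cx, cy) in enumerate(grid.centers):
            sel = ((np.abs(pts[:, 0] - cx) <= h) & (np.abs(pts[:, 1] - cy) <= h)
                   & np.isfinite(pts[:, 2]))
            if sel.any():
                out[k] = pts[sel, 2].mean()
    elif callable(fld):
        q = (np.arange(4) + 0.5) / 4.0 * 2.0 - 1.0   # symmetric 4x4 lattice
        qx, qy = np.meshgrid(q * h, q * h)
        offs = np.column_stack([qx.ravel(), qy.ravel()])
        pts = (grid.centers[:, None, :] + offs[None, :, :]).reshape(-1, 2)
        disp = np.asarray(fld(pts), float).reshape(grid.n, 16, 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = np.nanmean(disp[:, :, 1], axis=1)
        full = np.all(np.isfinite(disp[:, :, 1]), axis=1)
        out[~full & ~np.isfinite(out)] = np.nan
    else:
        raise TypeError("field must be a DisplacementMap or a callable")
    if not allow_partial and not np.all(np.isfinite(out)):
        raise ValueError("measurement cell without any displacement sample")
    return out


def objective_F(u_comp: np.ndarray, u_meas: np.ndarray) -> float:
    """Sum of squared differences of grid-averaged displacements (mm²)."""
    u_comp = np.asarray(u_comp, float)
    u_meas = np.asarray(u_meas, float)
    if u_comp.shape != u_meas.shape or u_comp.ndim != 1 or len(u_comp) < 1:
        raise ValueError("u_comp and u_meas must be equal-length vectors")
    return float(np.sum((u_comp - u_meas) ** 2))


def relative_difference(F: float, n: int, u_mean_meas: float) -> float:
    """Relative measured-vs-computed difference, percent:
    (sqrt(F) / n) / u_mean_meas x 100."""
    if n < 1:
        raise ValueError("need at least one grid element")
    if u_mean_meas <= 0:
        raise ValueError("mean absolute measured displacement must be positive")
    return float(np.sqrt(F) / n / u_mean_meas * 100.0)


def young_from_shear(C: float) -> float:
    """Young's modulus of an incompressible Neo-Hookean solid: E = 6 C."""
    if C <= 0:
        raise ValueError("shear modulus must be positive")
    return 6.0 * C


def tissue_compression(u_near_mm: float, u_far_mm: float) -> float:
    """Compression of the tissue between two landmarks on one axial line,
    from their measured axial displacements (mm): |u_far - u_near|."""
    return abs(float(u_far_mm) - float(u_near_mm))


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

@dataclass
class LatticeSpec:
    """Search lattice over (C_wall, C_intima) in kPa.

    Two-stage by default: a log-spaced coarse pass over ``bounds`` followed
    by a linear refinement spanning the coarse winner's neighbor interval.
    ``kind='linear'`` gives the literal single-stage constant-step lattice.
    """

    kind: str = "two_stage"
    coarse_n: int = 20
    refine_n: int = 9
    linear_n: int = 80
    bounds: tuple = (1.0, 400.0)

    def coarse_values(self) -> np.ndarray:
        if self.kind == "linear":
            return np.linspace(self.bounds[0], self.bounds[1], self.linear_n)
        return np.geomspace(self.bounds[0], self.bounds[1], self.coarse_n)

    def refine_values(self, winner: float) -> np.ndarray:
        coarse = self.coarse_values()
        i = int(np.argmin(np.abs(coarse - winner)))
        lo = coarse[max(i - 1, 0)]
        hi = coarse[min(i + 1, len(coarse) - 1)]
        return np.unique(np.concatenate([np.linspace(lo, hi, self.refine_n),
                                         [winner]]))


def _argmin_with_ties(Fvals, cw, ci):
    """Index of smallest F; ties broken by smaller C_wall then C_intima."""
    order = np.lexsort((ci, cw, Fvals))
    return order[0]


def _evaluate(forward, step, values_w, values_i, cache):
    out = {}
    for cw in values_w:
        for cival in values_i:
            key = (float(cw), float(cival))
            if key in cache:
                out[key] = cache[key]
                continue
            try:
                out[key] = np.asarray(forward(cw, cival, step), float)
            except ConvergenceError as exc:
                warnings.warn(f"forward solve failed at C_wall={cw:.3g}, "
                              f"C_intima={cival:.3g}: {exc}; point excluded",
                              RuntimeWarning, stacklevel=3)
                out[key] = None
            cache[key] = out[key]
    return out


def _select(evaluated, u_meas):
    keys = [k for k, v in evaluated.items() if v is not None]
    if not keys:
        raise ConvergenceError("no lattice point converged")
    mask = np.isfinite(u_meas)
    for k in keys:
        mask &= np.isfinite(evaluated[k])
    if not mask.any():
        raise ValueError("no measurement cell is covered by every candidate")
    Fv = np.array([objective_F(evaluated[k][mask], u_meas[mask]) for k in keys])
    cw = np.array([k[0] for k in keys])
    ci = np.array([k[1] for k in keys])
    best = _argmin_with_ties(Fv, cw, ci)
    return keys[best], Fv[best], int(mask.sum()), mask


def grid_search(forward, u_meas_per_step: dict,
                lattice: LatticeSpec | None = None,
                steps: tuple | None = None) -> list:
    """Exhaustive (C_wall, C_intima) search, independently per pressure step.

    ``forward(C_wall, C_intima, step)`` must return the computed grid-
    averaged axial displacement vector (mm; NaN allowed for uncovered
    cells); ``u_meas_per_step`` maps step_id to the measured vector.  Cells
    are compared over the common coverage of all candidates.  Lattice
    points whose forward solve fails are excluded with a warning.
    Returns one :class:`StiffnessEstimate` per step.
    """
    lattice = lattice or LatticeSpec()
    steps = steps or default_steps()
    results = []
    for step in steps:
        u_meas = np.asarray(u_meas_per_step[step.step_id], float)
        cache: dict = {}
        vals = lattice.coarse_values()
        t0 = time.perf_counter()
        evaluated = _evaluate(forward, step, vals, vals, cache)
        (cw0, ci0), F0, n0, _ = _select(evaluated, u_meas)
        log.info("step %d coarse pass: %d candidates in %.1fs, winner "
                 "(%.3g, %.3g)", step.step_id, len(evaluated),
                 time.perf_counter() - t0, cw0, ci0)
        if lattice.kind == "two_stage":
            rw = lattice.refine_values(cw0)
            ri = lattice.refine_values(ci0)
            evaluated = _evaluate(forward, step, rw, ri, cache)
            (cw0, ci0), F0, n0, mask = _select(evaluated, u_meas)
        else:
            mask = np.isfinite(u_meas)
        u_mean = float(np.mean(np.abs(u_meas[np.isfinite(u_meas)])))
        durel = relative_difference(F0, n0, u_mean) if u_mean > 0 else np.nan
        results.append(StiffnessEstimate(step, cw0, ci0, F0, durel, n0))
    return results


class FEForward:
    """Forward operator: candidate moduli -> computed grid-averaged axial
    displacements for one incremental pressure step.

    For each candidate the vessel is inflated from the unloaded reference
    to the step's start and end pressures with the candidate moduli; the
    incremental displacement field is interpolated in the deformed start-
    pressure configuration (where the measured pre-frame lives) and averaged
    over the fixed spatial measurement cells.

    The Neo-Hookean model obeys the exact scaling identity
    u(P, k C) = u(P / k, C) when every modulus scales together, so the
    operator solves one canonical problem (C_wall = 1 kPa) per modulus
    ratio C_intima / C_wall and serves all candidates on that ratio from a
    shared ascending pressure ladder of cached continuation states.  To
    keep the identity exact, buffer and calcium moduli are specified
    relative to the wall (their influence on the tissue displacement is
    negligible at these ratios).  Candidates whose canonical pressure
    P / C_wall exceeds ``max_canonical_pressure`` (inner stretches beyond
    ~3, where the quasi-static expansion branch leaves the solver's range)
    or whose solve diverges are excluded by the grid search.
    """

    def __init__(self, mesh, grid: MeasurementGrid,
                 options: SolverOptions | None = None,
                 calcium_ratio: float = 1.0e3, buffer_ratio: float = 1.0e-4,
                 max_canonical_pressure: float = 8.0,
                 base_pressure_mmhg: float = 10.0):
        from plaquemech.fem.solver import FEOperator
        self._FEOperator = FEOperator
        self.mesh = mesh
        self.grid = grid
        self.options = options or SolverOptions()
        # the mesh geometry is the (stress-free) configuration imaged at the
        # protocol start; loads are pressure increases above that baseline
        self.base_pressure_mmhg = base_pressure_mmhg
        self.calcium_ratio = calcium_ratio
        self.buffer_ratio = buffer_ratio
        self.max_canonical_pressure = max_canonical_pressure
        self._cache: dict = {}
        self._canon: dict = {}
        self.n_solves = 0
        # reference-configuration cell quadrature: locate the fixed 4x4
        # points per cell once; averaging a candidate field is then a
        # gather + dot with the barycentric weights
        h = grid.half_mm
        q = ((np.arange(4) + 0.5) / 4.0 * 2.0 - 1.0) * h
        qx, qy = np.meshgrid(q, q)
        offs = np.column_stack([qx.ravel(), qy.ravel()])
        pts = (grid.centers[:, None, :] + offs[None, :, :]).reshape(-1, 2)
        locator = FieldInterpolator(mesh.nodes, mesh.subtriangles(),
                                    np.zeros(mesh.n_nodes))
        tri_idx, bary = locator.locate(pts)
        if np.any(tri_idx < 0):
            raise ValueError("measurement cell outside the meshed tissue")
        self._q_nodes = locator.tris[tri_idx]        # (n*16, 3)
        self._q_bary = bary                          # (n*16, 3)

    def _ratio_entry(self, r: float):
        entry = self._canon.get(r)
        if entry is None:
            mat = MaterialMap(C_wall=1.0, C_intima=r,
                              C_calcium=max(self.calcium_ratio, 1.0, r),
                              C_buffer=self.buffer_ratio)
            entry = {"op": self._FEOperator(self.mesh, mat, self.options),
                     "states": {0.0: np.zeros((self.mesh.n_nodes, 2))},
                     "fail_q": np.inf}
            self._canon[r] = entry
        return entry

    def _canonical_state(self, r: float, q: float) -> np.ndarray:
        """Displacement of the canonical (C_wall = 1) problem at scaled
        pressure q (kPa), advancing the cached continuation ladder."""
        entry = self._ratio_entry(r)
        states = entry["states"]
        qr = round(q, 12)
        if qr in states:
            return states[qr]
        if q >= entry["fail_q"]:
            raise ConvergenceError(
                f"canonical pressure {q:.3g} kPa beyond convergence limit "
                f"for ratio {r:.3g}")
        if q > self.max_canonical_pressure:
            entry["fail_q"] = min(entry["fail_q"], q)
            raise ConvergenceError(
                f"canonical pressure {q:.3g} kPa exceeds the supported "
                f"range ({self.max_canonical_pressure:g} kPa)")
        q0 = max(p for p in states if p <= qr)

        def keep(p_now, u_now):
            states[round(p_now, 12)] = u_now.copy()

        try:
            u, its, _ = entry["op"].continue_to(states[q0], q0, q,
                                                on_state=keep)
        except ConvergenceError:
            entry["fail_q"] = min(entry["fail_q"], q)
            raise
        self.n_solves += 1
        states[qr] = u
        return u

    def __call__(self, C_wall: float, C_intima: float,
                 step: StepDefinition) -> np.ndarray:
        key = (float(C_wall), float(C_intima), step.step_id)
        if key in self._cache:
            return self._cache[key]
        r = round(float(C_intima) / float(C_wall), 12)
        if step.p_from_mmhg < self.base_pressure_mmhg:
            raise ValueError("step starts below the imaging base pressure")
        q_from = mmhg_to_kpa(step.p_from_mmhg - self.base_pressure_mmhg) \
            / float(C_wall)
        q_to = mmhg_to_kpa(step.p_to_mmhg - self.base_pressure_mmhg) \
            / float(C_wall)
        u_start = self._canonical_state(r, q_from)
        u_end = self._canonical_state(r, q_to)
        du_y = (u_end - u_start)[:, 1]
        q_vals = np.einsum("pc,pc->p", self._q_bary, du_y[self._q_nodes])
        vals = q_vals.reshape(self.grid.n, 16).mean(axis=1)
        self._cache[key] = vals
        return vals


def intima_sensitivity(forward, step: StepDefinition, C_wall: float,
                       C_intima_values: np.ndarray) -> float:
    """Relative spread (%) of computed grid displacements across the
    C_intima axis at fixed C_wall.

    Defined as max over candidate pairs of the RMS difference of the
    grid-averaged displacement vectors, normalized by the mean absolute
    displacement of the middle candidate.  Small values mean the objective
    cannot distinguish intima stiffness (thin-intima identifiability loss).
    """
    vecs = [np.asarray(forward(C_wall, ci, step), float)
            for ci in C_intima_values]
    mask = np.all([np.isfinite(v) for v in vecs], axis=0)
    ref = vecs[len(vecs) // 2][mask]
    scale = np.mean(np.abs(ref))
    worst = 0.0
    for a in range(len(vecs)):
        for b in range(a + 1, len(vecs)):
            rms = np.sqrt(np.mean((vecs[a][mask] - vecs[b][mask]) ** 2))
            worst = max(worst, rms / scale * 100.0)
    return worst
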