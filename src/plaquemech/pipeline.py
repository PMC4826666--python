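"""End-to-end synthetic inflation experiment and inversion.

Drives the whole loop: phantom generation, forward FE at the ground-truth
moduli per pressure step, scatterer displacement, RF simulation, speckle
tracking, measurement-grid averaging, and grid-search inversion.  All
randomness is seeded through the configuration; a rerun with the same
configuration is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

import plaquemech
from plaquemech import inverse as inv
from plaquemech import phantom, tracking, ultrasound
from plaquemech.fem import (FieldInterpolator, PressureProtocol, SolverOptions,
                            mesh_geometry)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_config"]

log = logging.getLogger("plaquemech.pipeline")


class PhantomConfig(BaseModel):
    lumen_radius: float = 1.5
    wall_thickness: float = 0.5
    intima_thickness_max: float = 2.0
    eccentricity: float = 0.6
    calcium_size_mm: Optional[float] = None
    calcium_angle_deg: float = -90.0
    n_vertices: int = 128
    center: tuple = (0.0, 6.0)
    seed: int = Field(..., description="phantom RNG seed (irregularity)")


class TruthConfig(BaseModel):
    """Ground-truth moduli of the synthetic specimen, kPa."""

    C_wall: float
    C_intima: float


class AcquisitionConfig(BaseModel):
    scatterer_density_per_mm2: float = 3000.0
    scatterer_seed: int = Field(...)
    noise_snr_db: Optional[float] = 30.0
    noise_seed: int = Field(...)
    fov_x_min_mm: float = -4.0
    fov_x_max_mm: float = 4.0
    fov_depth_mm: float = 11.0


class MeshConfig(BaseModel):
    target_edge: float = 0.15
    buffer_thickness: float = 2.0


class SolverConfig(BaseModel):
    formulation: str = "mixed"
    newton_tol: float = 1e-8
    max_newton: int = 25
    max_bisect: int = 8
    kappa_factor: float = 1e4

    def to_options(self) -> SolverOptions:
        return SolverOptions(self.formulation, self.newton_tol,
                             self.max_newton, self.max_bisect, self.kappa_factor)


class LatticeConfig(BaseModel):
    kind: str = "two_stage"
    coarse_n: int = 20
    refine_n: int = 9
    linear_n: int = 80
    bounds: tuple = (1.0, 400.0)

    def to_spec(self) -> inv.LatticeSpec:
        return inv.LatticeSpec(self.kind, self.coarse_n, self.refine_n,
                               self.linear_n, tuple(self.bounds))


class GridConfig(BaseModel):
    band_halfwidth: float = 0.25
    cell_size_um: float = 100.0


class RunConfig(BaseModel):
    """Validated configuration of a full synthetic run (units per field:
    mm for geometry, kPa for moduli, mmHg for pressures, µm for cells)."""

    phantom: PhantomConfig
    truth: TruthConfig
    acquisition: AcquisitionConfig
    mesh: MeshConfig = MeshConfig()
    solver: SolverConfig = SolverConfig()
    lattice: LatticeConfig = LatticeConfig()
    grid: GridConfig = GridConfig()
    steps_mmhg: list[tuple] = [(1, 10.0, 80.0), (2, 80.0, 100.0), (3, 100.0, 120.0)]
    tracking_roi_margin_mm: float = 0.75
    # quasi-static acquisition: RF frames are recorded along a geometric
    # pressure ladder so each tracked pair has small interframe motion
    max_pressure_ratio: float = 1.15
    min_increments: int = 2
    output_dir: str = "plaquemech_run"

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    return RunConfig(**yaml.safe_load(Path(path).read_text()))


class PipelineResult:
    """In-memory artifacts of a run."""

    def __init__(self):
        self.geometry = None
        self.mesh = None
        self.truth_solutions = {}
        self.displacement_maps = {}
        self.u_meas = {}
        self.estimates = []
        self.grid = None
        self.paths = {}

    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.estimates:
            rows.append({"step": e.step.step_id,
                         "p_from_mmhg": e.step.p_from_mmhg,
                         "p_to_mmhg": e.step.p_to_mmhg,
                         "C_wall_kpa": e.C_wall, "C_intima_kpa": e.C_intima,
                         "E_wall_kpa": e.E_wall, "E_intima_kpa": e.E_intima,
                         "F_mm2": e.F_mm2, "delta_u_rel_pct": e.delta_u_rel_pct,
                         "n_cells": e.n_cells})
        return pd.DataFrame(rows)


def _steps(config: RunConfig):
    return tuple(inv.StepDefinition(int(s[0]), float(s[1]), float(s[2]))
                 for s in config.steps_mmhg)


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute the full synthetic experiment defined by ``config``.

    Stages: phantom -> mesh -> truth forward FE per step -> scatterer
    displacement -> RF simulation (pre/post per step) -> tracking ->
    grid averaging -> grid-search inversion.  Artifacts are written under
    ``config.output_dir`` with a provenance sidecar when ``write``.
    """
    res = PipelineResult()
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    pc = config.phantom
    calc = None
    if pc.calcium_size_mm:
        calc = phantom.CalciumSpec(pc.calcium_size_mm, pc.calcium_angle_deg)
    geom = phantom.make_vessel_geometry(
        pc.lumen_radius, pc.wall_thickness, pc.intima_thickness_max,
        pc.eccentricity, calcium_spec=calc, n_vertices=pc.n_vertices,
        seed=pc.seed, center=tuple(pc.center))
    res.geometry = geom
    mesh = mesh_geometry(geom, config.mesh.target_edge, config.mesh.buffer_thickness)
    res.mesh = mesh
    grid = inv.build_measurement_grid(geom, config.grid.band_halfwidth,
                                      config.grid.cell_size_um)
    res.grid = grid

    steps = _steps(config)
    ac = config.acquisition
    scat = phantom.make_scatterers(geom, ac.scatterer_density_per_mm2,
                                   seed=ac.scatterer_seed)
    fov = ultrasound.FieldOfView(ac.fov_x_min_mm, ac.fov_x_max_mm, ac.fov_depth_mm)
    transducer = ultrasound.TransducerSpec()
    opts = config.solver.to_options()

    # tracking ROI: the measurement band plus margin
    ring_y = np.concatenate([geom.outer_contour[:, 1], geom.lumen_contour[:, 1]])
    m = config.tracking_roi_margin_mm
    roi = (geom.center[0] - config.grid.band_halfwidth - m,
           geom.center[0] + config.grid.band_halfwidth + m,
           max(ring_y.min() - m, 0.1), min(ring_y.max() + m, ac.fov_depth_mm - 0.1))

    # one quasi-static acquisition over the whole protocol: a geometric
    # pressure ladder through every step boundary keeps interframe motion
    # small; the boundaries are checkpoints for the cumulative maps
    levels = [steps[0].p_from_mmhg]
    boundary_index = {steps[0].p_from_mmhg: 0}
    for step in steps:
        n_inc = max(config.min_increments,
                    int(np.ceil(np.log(step.p_to_mmhg / step.p_from_mmhg)
                                / np.log(config.max_pressure_ratio))))
        seg = np.geomspace(step.p_from_mmhg, step.p_to_mmhg, n_inc + 1)[1:]
        levels.extend(seg.tolist())
        boundary_index[step.p_to_mmhg] = len(levels) - 1

    t = config.truth
    # buffer/calcium relative to the wall, matching the inverse operator;
    # the phantom geometry is the (stress-free) configuration at the first
    # protocol pressure, mirroring how the imaged 10 mmHg cross-section
    # becomes the FE reference
    mat = phantom.MaterialMap(
        C_wall=t.C_wall, C_intima=t.C_intima,
        C_calcium=1.0e3 * max(t.C_wall, t.C_intima),
        C_buffer=1.0e-4 * t.C_wall)
    base_kpa = PressureProtocol(np.array(levels[:1])).levels_kpa[0]
    ladder = PressureProtocol(np.array(levels))
    gauge = ladder.levels_kpa - base_kpa
    from plaquemech.fem.solver import FEOperator
    op = FEOperator(mesh, mat, opts)
    t0 = time.perf_counter()
    sols = []
    u_prev, p_prev = np.zeros((mesh.n_nodes, 2)), 0.0
    for pg in gauge:
        if pg == 0.0:
            sols.append(u_prev.copy())
            continue
        u_prev, _, _ = op.continue_to(u_prev, p_prev, pg)
        p_prev = pg
        sols.append(u_prev.copy())
    res.truth_solutions = {p: u for p, u in zip(levels, sols)}
    log.info("truth FE: %d levels in %.1fs", len(levels), time.perf_counter() - t0)

    ref_interp_tris = mesh.subtriangles()
    frames = []
    for i, u in enumerate(sols):
        interp = FieldInterpolator(mesh.nodes, ref_interp_tris, u)
        # 'nearest' covers scatterers in the µm-scale sliver between the
        # polygonal contour and the coarser mesh boundary
        moved = ultrasound.displace_scatterers(
            scat, lambda p: interp(p, outside="nearest"))
        frames.append(ultrasound.simulate_rf(
            moved, transducer, fov, noise_snr_db=ac.noise_snr_db,
            seed=ac.noise_seed + i))
    log.info("RF simulation: %d frames", len(frames))
    t0 = time.perf_counter()
    increments = []
    for i in range(len(frames) - 1):
        # the previous increment is a second offset hypothesis: in the
        # quasi-static sequence consecutive increments are similar
        increments.append(tracking.estimate_displacement(
            frames[i], frames[i + 1], roi_mm=roi,
            prior=increments[-1] if increments else None))
    log.info("tracking: %d pairs in %.1fs", len(increments),
             time.perf_counter() - t0)
    cumulative = tracking.accumulate_displacement(increments,
                                                  return_partials=True)

    def cum_map(p_mmhg):
        idx = boundary_index[p_mmhg]
        if idx == 0:
            base = cumulative[0]
            zero = np.zeros_like(base.axial_um)
            return tracking.DisplacementMap(zero, zero.copy(),
                                            base.grid_axial_step_um,
                                            base.grid_lateral_step_um,
                                            base.origin_mm)
        return cumulative[idx - 1]

    for step in steps:
        m_from = cum_map(step.p_from_mmhg)
        m_to = cum_map(step.p_to_mmhg)
        dmap = tracking.DisplacementMap(
            m_to.axial_um - m_from.axial_um,
            m_to.lateral_um - m_from.lateral_um,
            m_to.grid_axial_step_um, m_to.grid_lateral_step_um,
            m_to.origin_mm)
        res.displacement_maps[step.step_id] = dmap
        res.u_meas[step.step_id] = inv.average_on_grid(dmap, grid,
                                                       allow_partial=True)

    forward = inv.FEForward(mesh, grid, options=opts,
                            base_pressure_mmhg=steps[0].p_from_mmhg)
    t0 = time.perf_counter()
    res.estimates = inv.grid_search(forward, res.u_meas,
                                    config.lattice.to_spec(), steps)
    log.info("grid search: %d canonical solves in %.1fs", forward.n_solves,
             time.perf_counter() - t0)

    if write:
        phantom.write_geometry(geom, out / "geometry.json")
        phantom.write_scatterers(scat, out / "scatterers.csv")
        for sid, dmap in res.displacement_maps.items():
            tracking.write_displacement_map(dmap, out / f"displacement_step{sid}")
        df = res.estimates_frame()
        df.to_csv(out / "estimates.csv", index=False)
        provenance = {"config_hash": config.config_hash(),
                      "version": plaquemech.__version__,
                      "config": config.model_dump()}
        (out / "provenance.json").write_text(json.dumps(provenance, default=str))
        res.paths = {"geometry": out / "geometry.json",
                     "estimates": out / "estimates.csv",
                     "provenance": out / "provenance.json"}
    return res
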