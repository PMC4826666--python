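"""Finite elements: meshing, constitutive law, solver, analytic oracle."""

import numpy as np
import pytest

from plaquemech import phantom
from plaquemech.errors import MeshingError
from plaquemech.fem import (FieldInterpolator, PressureProtocol, SolverOptions,
                            analytic_tube_inflation, deformed_tissue_area,
                            interpolate_displacement, linear_tube_expansion,
                            mesh_geometry, solve_inflation, strain_energy_density)
from plaquemech.fem.solver import FEOperator
from plaquemech.units import kpa_to_mmhg


def lumen_radii(mesh, geometry, u=None):
    nodes = np.unique(mesh.lumen_edges)
    x = mesh.nodes[nodes] + (0 if u is None else u[nodes])
    return np.linalg.norm(x - geometry.center, axis=1)


class TestMesh:
    def test_sanity_positive_areas_and_labels(self, concentric_mesh):
        assert np.all(concentric_mesh.corner_areas() > 0)
        assert set(np.unique(concentric_mesh.region)) == {"intima", "wall", "buffer"}

    def test_refinement_scales_element_count(self, concentric_geometry):
        coarse = mesh_geometry(concentric_geometry, target_edge=0.3)
        fine = mesh_geometry(concentric_geometry, target_edge=0.15)
        ratio = fine.n_elements / coarse.n_elements
        assert 3.0 < ratio < 5.0

    def test_calcium_label_area_matches_polygon(self):
        g = phantom.make_vessel_geometry(
            1.5, 0.5, 1.5, 0.0, calcium_spec=phantom.CalciumSpec(0.6, 90.0))
        mesh = mesh_geometry(g, target_edge=0.06)
        from plaquemech._geom import shoelace_area
        target = shoelace_area(g.calcium_regions[0])
        labeled = mesh.region_area("calcium")
        assert labeled == pytest.approx(target, rel=0.05)

    def test_degenerate_parameters_rejected(self, concentric_geometry):
        with pytest.raises(MeshingError):
            mesh_geometry(concentric_geometry, target_edge=-0.1)

    def test_region_area_matches_geometry(self, concentric_mesh, concentric_geometry):
        areas = concentric_geometry.region_areas()
        # straight-edge polygonalization of the circular contours makes the
        # mesh area slightly smaller; 1% at this angular resolution
        assert concentric_mesh.region_area("intima") == pytest.approx(
            areas["intima"], rel=0.01)
        assert concentric_mesh.region_area("wall") == pytest.approx(
            areas["wall"], rel=0.01)


class TestStrainEnergy:
    def test_undeformed_is_zero(self):
        assert strain_energy_density(10.0, np.eye(2)) == 0.0

    def test_simple_shear_closed_form(self):
        F = np.array([[1.0, 0.5], [0.0, 1.0]])
        assert strain_energy_density(10.0, F) == pytest.approx(2.5)

    def test_nonnegative_for_isochoric_deformations(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            F = np.eye(2) + 0.5 * rng.standard_normal((2, 2))
            det = np.linalg.det(F)
            if det <= 0:
                continue
            F /= np.sqrt(det)
            assert strain_energy_density(3.0, F) >= -1e-12

    def test_inverted_state_rejected(self):
        with pytest.raises(ValueError):
            strain_energy_density(1.0, np.diag([1.0, -1.0]))


class TestAnalyticTube:
    def test_zero_pressure_identity(self):
        assert analytic_tube_inflation(50.0, 1.5, 2.5, 0.0) == 1.5

    def test_small_load_matches_lame(self):
        C, A, B = 50.0, 1.5, 2.5
        P = 0.05
        a = analytic_tube_inflation(C, A, B, P)
        assert (a - A) == pytest.approx(linear_tube_expansion(C, A, B, P),
                                        rel=0.02)

    def test_monotone_in_pressure(self):
        radii = [analytic_tube_inflation(50.0, 1.5, 2.5, P)
                 for P in (1.0, 4.0, 8.0, 14.0)]
        assert np.all(np.diff(radii) > 0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            analytic_tube_inflation(50.0, 2.5, 1.5, 1.0)


class TestSolver:
    def test_zero_pressure_zero_displacement(self, concentric_mesh):
        mat = phantom.MaterialMap(50.0, 50.0)
        op = FEOperator(concentric_mesh, mat)
        u, its, _ = op.continue_to(np.zeros((concentric_mesh.n_nodes, 2)),
                                   0.0, 0.0)
        assert np.allclose(u, 0.0)

    def test_homogeneous_tube_matches_analytic(self, concentric_geometry):
        mesh = mesh_geometry(concentric_geometry, target_edge=0.15)
        mat = phantom.MaterialMap(50.0, 50.0)
        P = 13.3322
        sols = solve_inflation(mesh, mat,
                               PressureProtocol(np.array([kpa_to_mmhg(P)])))
        a_fe = lumen_radii(mesh, concentric_geometry,
                           sols[0].nodal_displacements).mean()
        a_an = analytic_tube_inflation(50.0, 1.5, 3.25, P)
        assert abs(a_fe - a_an) / (a_an - 1.5) < 0.01

    def test_stiffer_material_displaces_less(self, concentric_mesh,
                                             concentric_geometry):
        P = kpa_to_mmhg(8.0)
        prot = PressureProtocol(np.array([P]))
        soft = solve_inflation(concentric_mesh, phantom.MaterialMap(50.0, 10.0),
                               prot)[0]
        stiff = solve_inflation(concentric_mesh, phantom.MaterialMap(100.0, 20.0),
                                prot)[0]
        lum = np.unique(concentric_mesh.lumen_edges)
        mag_soft = np.linalg.norm(soft.nodal_displacements[lum], axis=1)
        mag_stiff = np.linalg.norm(stiff.nodal_displacements[lum], axis=1)
        assert np.all(mag_stiff < mag_soft)

    def test_modulus_pressure_scaling_law(self, concentric_mesh):
        opts = SolverOptions()
        u0 = np.zeros((concentric_mesh.n_nodes, 2))
        k = 4.0
        base = phantom.MaterialMap(40.0, 8.0, C_calcium=4.0e4, C_buffer=0.008)
        scaled = phantom.MaterialMap(40.0 * k, 8.0 * k, C_calcium=4.0e4 * k,
                                     C_buffer=0.008 * k)
        ub, _, _ = FEOperator(concentric_mesh, base, opts).continue_to(u0, 0, 2.5)
        us, _, _ = FEOperator(concentric_mesh, scaled, opts).continue_to(u0, 0, 10.0)
        assert np.allclose(ub, us, atol=1e-10)

    def test_mixed_and_penalty_agree(self, concentric_mesh):
        u0 = np.zeros((concentric_mesh.n_nodes, 2))
        mat = phantom.MaterialMap(50.0, 10.0)
        um, _, _ = FEOperator(concentric_mesh, mat,
                              SolverOptions("mixed")).continue_to(u0, 0, 10.0)
        up, _, _ = FEOperator(concentric_mesh, mat,
                              SolverOptions("penalty")).continue_to(u0, 0, 10.0)
        scale = np.abs(um).max()
        assert np.abs(um - up).max() / scale < 0.01

    def test_tissue_nearly_incompressible(self, concentric_mesh):
        mat = phantom.MaterialMap(50.0, 10.0)
        sols = solve_inflation(concentric_mesh, mat, PressureProtocol.default())
        a0 = concentric_mesh.region_area("intima", "wall", "calcium")
        a1 = deformed_tissue_area(concentric_mesh,
                                  sols[-1].nodal_displacements)
        assert abs(a1 - a0) / a0 < 0.005

    def test_mesh_convergence_on_lumen_displacement(self, concentric_geometry):
        mat = phantom.MaterialMap(50.0, 50.0)
        prot = PressureProtocol(np.array([kpa_to_mmhg(10.0)]))
        expansions = []
        for edge in (0.3, 0.15):
            mesh = mesh_geometry(concentric_geometry, target_edge=edge)
            sol = solve_inflation(mesh, mat, prot)[0]
            r = lumen_radii(mesh, concentric_geometry, sol.nodal_displacements)
            expansions.append(r.mean() - 1.5)
        assert abs(expansions[1] - expansions[0]) / expansions[1] < 0.01

    def test_buffer_stiffness_insensitivity(self, concentric_mesh,
                                            concentric_geometry):
        prot = PressureProtocol(np.array([kpa_to_mmhg(10.0)]))
        expansions = []
        for cb in (0.001, 0.1):
            mat = phantom.MaterialMap(50.0, 50.0, C_buffer=cb)
            sol = solve_inflation(concentric_mesh, mat, prot)[0]
            r = lumen_radii(concentric_mesh, concentric_geometry,
                            sol.nodal_displacements)
            expansions.append(r.mean() - 1.5)
        assert abs(expansions[1] - expansions[0]) / expansions[0] < 0.005


class TestPressureProtocol:
    def test_default_levels_and_conversion(self):
        prot = PressureProtocol.default()
        assert prot.levels_mmhg.tolist() == [10.0, 80.0, 100.0, 120.0]
        assert prot.levels_kpa[0] == pytest.approx(1.33322)

    @pytest.mark.parametrize("levels", [[], [50.0, 40.0], [-5.0, 10.0]])
    def test_invalid_protocols_rejected(self, levels):
        with pytest.raises(ValueError):
            PressureProtocol(np.array(levels))


class TestInterpolation:
    def test_exact_at_nodes_and_linear_fields(self, concentric_mesh):
        mesh = concentric_mesh
        u = np.column_stack([0.3 * mesh.nodes[:, 0] + 0.1,
                             -0.2 * mesh.nodes[:, 1] + 0.05])
        some_nodes = mesh.nodes[::97]
        vals = interpolate_displacement(u, mesh, some_nodes)
        assert np.allclose(vals, u[::97], atol=1e-12)
        rng = np.random.default_rng(0)
        pts = rng.uniform([-2.5, 2.5], [2.5, 7.5], size=(200, 2))
        from shapely import contains_xy
        from plaquemech._geom import to_polygon
        inside = contains_xy(to_polygon(mesh.nodes[np.unique(mesh.lumen_edges)]
                                        ).buffer(0.0), pts[:, 0], pts[:, 1])
        # linear fields are reproduced exactly by barycentric interpolation
        vals = interpolate_displacement(u, mesh, pts, outside="nan")
        ok = np.all(np.isfinite(vals), axis=1)
        expected = np.column_stack([0.3 * pts[ok, 0] + 0.1,
                                    -0.2 * pts[ok, 1] + 0.05])
        assert np.allclose(vals[ok], expected, atol=1e-12)

    def test_outside_point_raises(self, concentric_mesh):
        with pytest.raises(ValueError):
            interpolate_displacement(np.zeros_like(concentric_mesh.nodes),
                                     concentric_mesh,
                                     np.array([[50.0, 50.0]]))

    def test_field_interpolator_refinement_bound(self, concentric_geometry):
        # interpolation error of a smooth field shrinks with element size
        errs = []
        for edge in (0.4, 0.2):
            mesh = mesh_geometry(concentric_geometry, target_edge=edge)
            f = np.sin(mesh.nodes[:, 0]) * np.cos(mesh.nodes[:, 1])
            interp = FieldInterpolator(mesh.nodes, mesh.subtriangles(), f)
            pts = np.column_stack([np.zeros(50),
                                   np.linspace(2.0, 3.2, 50)])
            exact = np.sin(pts[:, 0]) * np.cos(pts[:, 1])
            errs.append(np.abs(interp(pts) - exact).max())
        assert errs[1] < errs[0]


def test_vtk_export_round_numbers(tmp_path, concentric_mesh):
    from plaquemech.fem import write_vtk
    u = np.zeros_like(concentric_mesh.nodes)
    path = tmp_path / "mesh.vtk"
    write_vtk(concentric_mesh, path, point_data={"displacement": u})
    text = path.read_text()
    assert f"POINTS {concentric_mesh.n_nodes} double" in text
    assert f"CELL_TYPES {concentric_mesh.n_elements}" in text
    assert "VECTORS displacement double" in text
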