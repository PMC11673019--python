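import numpy as np
import pytest

from voct.fem import (
    HEALTHY_GEOMETRY,
    HEALTHY_MATERIAL,
    KC_GEOMETRY,
    KC_MATERIAL,
    CorneaGeometry,
    LoadCase,
    MaterialProperties,
    build_geometry,
    clamped_plate_reference,
    deflection_summary,
    mesh_cornea,
    solve_static,
)


class TestGeometry:
    def test_thickness_profile_endpoints(self):
        g = HEALTHY_GEOMETRY
        assert g.thickness(0.0) == pytest.approx(g.central_thickness_um)
        assert g.thickness(g.rim_radius_mm) == pytest.approx(g.peripheral_thickness_um)

    @pytest.mark.parametrize("geom", [HEALTHY_GEOMETRY, KC_GEOMETRY])
    def test_thickness_monotone_centre_to_edge(self, geom):
        r = np.linspace(0.0, geom.rim_radius_mm, 50)
        t = geom.thickness(r)
        assert np.all(np.diff(t) >= 0)

    def test_kc_relation_enforced(self):
        with pytest.raises(ValueError, match="central"):
            build_geometry(600.0, 750.0, label="kc", healthy_reference=HEALTHY_GEOMETRY)
        with pytest.raises(ValueError, match="peripheral"):
            build_geometry(450.0, 600.0, label="kc", healthy_reference=HEALTHY_GEOMETRY)

    def test_anterior_radius_must_cover_semi_diameter(self):
        with pytest.raises(ValueError):
            CorneaGeometry(550.0, 700.0, corneal_diameter_mm=11.5, anterior_radius_mm=5.0)


class TestMesh:
    def test_element_budget_within_ten_percent(self):
        mesh = mesh_cornea(HEALTHY_GEOMETRY, 1024)
        assert abs(mesh.n_elements - 1024) <= 0.1 * 1024

    def test_coarse_floor(self):
        mesh = mesh_cornea(HEALTHY_GEOMETRY, 16)
        assert mesh.n_elements >= 4
        with pytest.raises(ValueError):
            mesh_cornea(HEALTHY_GEOMETRY, 8)

    def test_fourfold_refinement_scales_node_count(self):
        coarse = mesh_cornea(HEALTHY_GEOMETRY, 256)
        fine = mesh_cornea(HEALTHY_GEOMETRY, 1024)
        assert fine.n_nodes / coarse.n_nodes == pytest.approx(4.0, rel=0.15)


class TestSolveStatic:
    def test_zero_pressure_zero_displacement(self):
        mesh = mesh_cornea(HEALTHY_GEOMETRY, 64)
        field = solve_static(mesh, HEALTHY_MATERIAL, LoadCase(iop_pa=0.0))
        assert np.all(field.displacement == 0.0)

    def test_linearity_in_pressure_and_compliance(self):
        mesh = mesh_cornea(HEALTHY_GEOMETRY, 64)
        base = solve_static(mesh, HEALTHY_MATERIAL, LoadCase(iop_pa=2000.0))
        double_p = solve_static(mesh, HEALTHY_MATERIAL, LoadCase(iop_pa=4000.0))
        assert np.allclose(double_p.displacement, 2.0 * base.displacement, rtol=1e-8)
        half_e = MaterialProperties(HEALTHY_MATERIAL.elastic_modulus_mpa / 2.0)
        soft = solve_static(mesh, half_e, LoadCase(iop_pa=2000.0))
        assert np.allclose(soft.displacement, 2.0 * base.displacement, rtol=1e-8)

    def test_clamped_boundary_nodes_do_not_move(self):
        mesh = mesh_cornea(KC_GEOMETRY, 256)
        field = solve_static(mesh, KC_MATERIAL, LoadCase())
        assert np.all(field.displacement[mesh.rim_nodes] == 0.0)

    def test_axis_nodes_have_no_radial_motion(self):
        mesh = mesh_cornea(HEALTHY_GEOMETRY, 256)
        field = solve_static(mesh, HEALTHY_MATERIAL, LoadCase())
        assert np.all(field.displacement[mesh.axis_nodes, 0] == 0.0)

    def test_solution_invariant_under_axial_translation(self):
        """Shifting the z origin of the section leaves the solved
        displacements unchanged (coordinate-convention check)."""
        a = mesh_cornea(HEALTHY_GEOMETRY, 64)
        b = mesh_cornea(HEALTHY_GEOMETRY, 64)
        b.nodes = b.nodes + np.array([0.0, 2.5e-3])
        ua = solve_static(a, HEALTHY_MATERIAL, LoadCase()).displacement
        ub = solve_static(b, HEALTHY_MATERIAL, LoadCase()).displacement
        assert np.allclose(ua, ub, rtol=1e-8, atol=1e-15)


class TestPlateReference:
    def test_zero_pressure(self):
        assert clamped_plate_reference(5e-3, 550e-6, 3.1e6, 0.42, 0.0) == 0.0

    def test_quartic_radius_scaling(self):
        w1 = clamped_plate_reference(5e-3, 550e-6, 3.1e6, 0.42, 2000.0)
        w2 = clamped_plate_reference(10e-3, 550e-6, 3.1e6, 0.42, 2000.0)
        assert w2 / w1 == pytest.approx(16.0)

    def test_closed_form_value(self):
        d = 3.1e6 * 550e-6**3 / (12 * (1 - 0.42**2))
        expected = 2000.0 * 5e-3**4 / (64 * d)
        assert clamped_plate_reference(5e-3, 550e-6, 3.1e6, 0.42, 2000.0) == pytest.approx(
            expected
        )


@pytest.fixture(scope="module")
def fields():
    load = LoadCase()
    fh = solve_static(mesh_cornea(HEALTHY_GEOMETRY, 256), HEALTHY_MATERIAL, load)
    fk = solve_static(mesh_cornea(KC_GEOMETRY, 256), KC_MATERIAL, load)
    return fh, fk


class TestCorneaDeflection:
    def test_maximum_deflection_at_apex(self, fields):
        for f in fields:
            assert f.max_deflection_radius_m == 0.0

    def test_kc_deflects_more_than_healthy(self, fields):
        fh, fk = fields
        assert fk.central_deflection_m > fh.central_deflection_m

    def test_identical_inputs_give_unit_ratio(self, fields):
        fh, _ = fields
        assert deflection_summary(fh, fh)["kc_to_healthy_ratio"] == pytest.approx(1.0)

    def test_fixed_geometry_ratio_is_modulus_ratio(self):
        """With identical geometry the deflection ratio reduces to the
        modulus ratio 3.1/2.4 by linearity."""
        mesh = mesh_cornea(HEALTHY_GEOMETRY, 64)
        load = LoadCase()
        fh = solve_static(mesh, HEALTHY_MATERIAL, load)
        fk = solve_static(mesh, KC_MATERIAL, load)
        ratio = deflection_summary(fh, fk)["kc_to_healthy_ratio"]
        assert ratio == pytest.approx(3.1 / 2.4, rel=1e-8)
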