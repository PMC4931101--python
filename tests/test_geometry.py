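"""Eye-mesh generator tests: dimensions, topology, fibres, scenarios."""

import dataclasses

import numpy as np
import pytest

from sbsim.geometry import (
    ConfigurationError,
    EyeGeometryConfig,
    base_cases,
    build_eye_mesh,
    build_sphere_mesh,
    compute_axial_length,
    corneal_apex_curvature,
    enumerate_scenarios,
)


@pytest.fixture(scope="module")
def eye():
    return build_eye_mesh()


class TestDimensions:
    def test_axial_length_matches_configured_axial_diameter(self, eye):
        assert compute_axial_length(eye) == pytest.approx(24.86, abs=1e-9)

    def test_axial_length_rigid_translation_invariant(self, eye):
        shifted = eye.nodes + np.array([1.3, -0.7, 2.0])
        assert compute_axial_length(eye, shifted) == pytest.approx(compute_axial_length(eye))

    def test_axial_length_scales_linearly(self, eye):
        assert compute_axial_length(eye, 1.01 * eye.nodes) == pytest.approx(25.109, abs=1e-3)

    def test_resolution_independence_of_axial_length(self, eye):
        finer = build_eye_mesh(resolution=1.5)
        assert abs(compute_axial_length(finer) - compute_axial_length(eye)) <= 1e-3

    def test_corneal_surface_on_ellipsoid(self, eye):
        """Cornea nodes satisfy the configured ellipsoid equation."""
        cfg = eye.config
        a, b, c = cfg.cornea_semiaxes
        apex = eye.nodes[eye.apex_node]
        center = apex - np.array([0.0, 0.0, c])
        ids = eye.region_map["cornea"]
        # restrict to nodes clearly inside the corneal cap (not the blend)
        ids = ids[eye.arc_from_limbus[ids] < -cfg.limbus_width]
        rel = eye.nodes[ids] - center
        q = (rel[:, 0] / a) ** 2 + (rel[:, 1] / b) ** 2 + (rel[:, 2] / c) ** 2
        assert np.abs(q - 1.0).max() < 1e-6


class TestTopology:
    def test_globe_is_topological_sphere(self, eye):
        assert eye.euler_characteristic("globe") == 2

    def test_lens_is_topological_sphere(self, eye):
        assert eye.euler_characteristic("lens") == 2

    def test_no_degenerate_elements(self, eye):
        assert eye.element_areas().min() > 1e-8

    def test_outward_orientation(self, eye):
        """Both closed components enclose positive signed volume."""
        from sbsim.geometry import _component_volume

        v_globe = _component_volume(eye.nodes, eye.elements[eye.globe_elements])
        v_lens = _component_volume(eye.nodes, eye.elements[eye.lens_elements])
        assert v_globe > 5000.0  # mm^3, eye-sized
        assert 0.0 < v_lens < 200.0

    def test_all_regions_present(self, eye):
        assert set(np.unique(eye.element_region)) == {"cornea", "limbus", "sclera", "nerve", "lens"}

    def test_sphere_mesh_closed(self):
        s = build_sphere_mesh(radius=10.0, n_phi=12, n_theta=8)
        assert s.euler_characteristic("globe") == 2


class TestThicknessAndBand:
    def test_scleral_thickness_interpolates_anchors(self, eye):
        arcs = eye.arc_from_limbus
        near_limbus = np.flatnonzero((arcs >= 0) & (arcs < 0.1))
        assert eye.thickness[near_limbus] == pytest.approx(0.80, abs=0.02)
        near_equator = np.flatnonzero(np.abs(arcs - 12.5) < 0.1)
        assert eye.thickness[near_equator] == pytest.approx(0.49, abs=0.02)

    def test_corneal_thickness_is_central_value(self, eye):
        ids = eye.region_map["cornea"]
        ids = ids[eye.arc_from_limbus[ids] < -eye.config.limbus_width]
        assert eye.thickness[ids] == pytest.approx(0.550, abs=1e-9)

    def test_band_candidate_ring_location(self, eye):
        arcs = eye.arc_from_limbus[eye.region_map["band_candidate"]]
        assert arcs.min() >= 11.0 and arcs.max() <= 14.0
        assert np.any((arcs >= 12.0) & (arcs <= 13.0))

    def test_band_window_ring_density(self, eye):
        """At least 3 node rings per mm under the band site."""
        arcs = eye.arc_from_limbus
        window = np.unique(np.round(arcs[(arcs > 11.0) & (arcs < 14.0)], 9))
        assert len(window) >= 3 * 3.0  # 3 mm window


class TestFibers:
    def test_corneal_families_orthogonal(self, eye):
        cor = eye.element_region == "cornea"
        dots = (eye.fiber_m[cor] * eye.fiber_n[cor]).sum(1)
        assert np.abs(dots).max() < 1e-8

    def test_fibres_tangent_to_surface(self, eye):
        normals = eye.element_normals()
        for fam in (eye.fiber_m, eye.fiber_n):
            active = np.linalg.norm(fam, axis=1) > 0.5
            assert np.abs((fam[active] * normals[active]).sum(1)).max() < 1e-8

    def test_limbus_fibres_circumferential(self, eye):
        """Circumferential family: no meridional (z-ward in-plane) component."""
        lim = eye.element_region == "limbus"
        m = eye.fiber_m[lim]
        normals = eye.element_normals()[lim]
        cent = eye.nodes[eye.elements].mean(axis=1)[lim]
        e_phi = np.stack([-cent[:, 1], cent[:, 0], np.zeros(len(cent))], 1)
        e_phi /= np.linalg.norm(e_phi, axis=1, keepdims=True)
        meridian = np.cross(normals, e_phi)
        meridian /= np.linalg.norm(meridian, axis=1, keepdims=True)
        assert np.abs((m * meridian).sum(1)).max() < 0.02

    def test_sclera_has_no_active_fibres(self, eye):
        scl = eye.element_region == "sclera"
        assert np.all(np.linalg.norm(eye.fiber_m[scl], axis=1) == 0.0)
        assert np.all(np.linalg.norm(eye.fiber_n[scl], axis=1) == 0.0)


class TestCurvature:
    def test_closed_form_apical_radius(self, eye):
        assert corneal_apex_curvature(eye, "NT") == pytest.approx(10.43**2 / 14.26, rel=1e-9)
        assert corneal_apex_curvature(eye, "SI") == pytest.approx(10.27**2 / 14.26, rel=1e-9)

    def test_spherical_cornea_degenerates_to_radius(self, eye):
        cfg = dataclasses.replace(eye.config, cornea_semiaxes=(7.8, 7.8, 7.8))
        spherical = dataclasses.replace(eye, config=cfg)
        assert corneal_apex_curvature(spherical, "NT") == pytest.approx(7.8)

    def test_quadric_fit_matches_closed_form(self, eye):
        fitted = corneal_apex_curvature(eye, "NT", method="fit")
        assert fitted == pytest.approx(corneal_apex_curvature(eye, "NT"), rel=0.01)


class TestScenarios:
    def test_combination_count(self):
        assert len(enumerate_scenarios()) == 27
        assert len(base_cases()) == 9

    def test_case_table_order(self):
        cases = base_cases()
        assert cases[0] == (1, 2.5, 11.0)
        assert cases[8] == (9, 1.0, 18.0)

    def test_each_case_has_three_tightening_levels(self):
        sc = enumerate_scenarios()
        for cid in range(1, 10):
            levels = sorted(s.tightening_pct for s in sc if s.case_id == cid)
            assert levels == [33.0, 67.0, 100.0]


class TestValidation:
    def test_under_resolved_band_rejected(self):
        with pytest.raises(ConfigurationError):
            build_eye_mesh(resolution=0.2)

    def test_negative_dimension_rejected(self):
        with pytest.raises(ConfigurationError):
            EyeGeometryConfig(central_corneal_thickness=-0.5)

    def test_unsorted_thickness_anchors_rejected(self):
        with pytest.raises(ConfigurationError):
            EyeGeometryConfig(scleral_thickness_profile=((5.0, 0.5), (1.0, 0.6)))
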