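"""Ray-tracing engine: exact conic intersection, exact Snell refraction,
tracing invariants, the ISO best-focus criterion, and power solving."""
import math

import numpy as np
import pytest

from iolray.biometry import BiometryRecord, IOLGeometry
from iolray.elp import ElpConfig, ElpPrediction, predict_iol_position
from iolray.errors import (GeometryError, PupilClipError, RayEscapeError)
from iolray.raytrace import (EyeModel, Ray, RayTraceConfig, Surface,
                             best_focus_refraction, build_pseudophakic_eye,
                             intersect_conic, interpolate_geometry,
                             predict_refraction_raytrace, refract_snell,
                             solve_iol_power_raytrace,
                             stiles_crawford_weight, trace_to_retina)
from iolray.thinlens import calc_formula

from _oracles import conic_sag_oracle, paraxial_refraction_oracle


def make_eye(record, iol, power=21.0, config=RayTraceConfig(), k=None):
    geometry = interpolate_geometry(iol, power)
    elp = predict_iol_position(record, geometry, "auto", ElpConfig(), iol)
    return build_pseudophakic_eye(record, geometry, elp, config, k_d=k)


class TestConicIntersection:
    SPHERE = Surface(z_vertex=10.0, radius=7.7, n_before=1.0, n_after=1.336)

    def test_axial_ray_hits_the_vertex(self):
        y, z, ny, nz = intersect_conic(Ray(0.0, 0.0, 0.0), self.SPHERE)
        assert (y, z) == (0.0, 10.0)
        assert abs(ny) < 1e-15 and nz == pytest.approx(-1.0)

    def test_spherical_sag_matches_closed_form(self):
        y, z, *_ = intersect_conic(Ray(1.0, 0.0, 0.0), self.SPHERE)
        assert z - 10.0 == pytest.approx(conic_sag_oracle(1.0, 7.7),
                                         abs=1e-12)
        assert conic_sag_oracle(1.0, 7.7) == pytest.approx(0.065211,
                                                           abs=1e-6)

    def test_parabolic_sag_is_quadratic(self):
        para = Surface(z_vertex=5.0, radius=7.7, q=-1.0, n_before=1.0,
                       n_after=1.5)
        for h in (0.5, 1.0, 2.0, 3.5):
            _, z, *_ = intersect_conic(Ray(h, 0.0, 0.0), para)
            assert z - 5.0 == pytest.approx(h * h / (2 * 7.7), abs=1e-12)

    def test_aperture_violation_raises(self):
        small = Surface(z_vertex=10.0, radius=7.7, n_before=1.0,
                        n_after=1.336, half_aperture=1.0)
        with pytest.raises(RayEscapeError):
            intersect_conic(Ray(2.0, 0.0, 0.0), small)


class TestSnell:
    FLAT_NORMAL = (0.0, -1.0)

    def test_matched_indices_leave_direction_unchanged(self):
        out = refract_snell(Ray(1.0, 0.0, 0.3), self.FLAT_NORMAL, 1.5, 1.5)
        assert out.u == pytest.approx(0.3, abs=1e-15)

    def test_thirty_degrees_into_glass(self):
        u = math.tan(math.radians(30.0))
        out = refract_snell(Ray(0.0, 0.0, u), self.FLAT_NORMAL, 1.0, 1.5)
        theta2 = math.degrees(math.atan(out.u))
        assert math.sin(math.radians(theta2)) == pytest.approx(1.0 / 3.0,
                                                               abs=1e-12)
        assert theta2 == pytest.approx(19.471, abs=1e-3)

    def test_normal_incidence_is_undeviated(self):
        out = refract_snell(Ray(0.0, 0.0, 0.0), self.FLAT_NORMAL, 1.0, 1.5)
        assert out.u == 0.0

    def test_total_internal_reflection_raises(self):
        u = math.tan(math.radians(45.0))   # past the ~41.8 deg critical angle
        with pytest.raises(RayEscapeError):
            refract_snell(Ray(0.0, 0.0, u), self.FLAT_NORMAL, 1.5, 1.0)


class TestEyeConstruction:
    def test_surface_layout_hand_arithmetic(self, normal_eye_record):
        geometry = IOLGeometry(r_front=8.0, r_back=-8.0, thickness=0.9,
                               n_iol=1.46)
        elp = ElpPrediction.from_center(4.9, 0.9, "mean")
        eye = build_pseudophakic_eye(normal_eye_record, geometry, elp)
        zs = [s.z_vertex for s in eye.surfaces]
        assert zs == pytest.approx([0.0, 0.54, 4.99, 5.89], abs=1e-9)
        assert eye.retina_z == 23.5

    def test_all_spherical_wide_aperture_eye_is_valid(self, generic_iol,
                                                      normal_eye_record):
        eye = make_eye(normal_eye_record, generic_iol)
        assert all(s.q == 0.0 for s in eye.surfaces)

    def test_lens_position_beyond_retina_is_geometry_error(
            self, normal_eye_record):
        geometry = IOLGeometry(r_front=8.0, r_back=-8.0, thickness=0.9,
                               n_iol=1.46)
        elp = ElpPrediction.from_center(23.5, 0.9, "mean")
        with pytest.raises(GeometryError):
            build_pseudophakic_eye(normal_eye_record, geometry, elp)


class TestTracing:
    def test_axial_ray_stays_on_axis(self, generic_iol, normal_eye_record):
        eye = make_eye(normal_eye_record, generic_iol)
        y, _ = trace_to_retina(eye, Ray(0.0, -5.0, 0.0))
        assert y == 0.0

    def test_single_surface_focal_length(self):
        # flatten everything but the corneal vertex (matched indices make
        # the other surfaces optically inert): paraxial focus at
        # n2*R/(n2-n1) = 1.336*7.7/0.336 = 30.617 mm from the vertex
        inert = 1.336
        eye = EyeModel(
            surfaces=(
                Surface(0.0, 7.7, 1.0, inert),
                Surface(1.0, 1e6, inert, inert),
                Surface(2.0, 1e6, inert, inert),
                Surface(3.0, 1e6, inert, inert)),
            pupil_z=1.5, pupil_diameter=6.0, retina_z=40.0)
        y0 = 1e-4
        y_ret, path = trace_to_retina(eye, Ray(y0, -1.0, 0.0))
        (y4, z4), (yr, zr) = path[-2], path[-1]
        u = (yr - y4) / (zr - z4)
        crossing = z4 - y4 / u
        assert crossing == pytest.approx(1.336 * 7.7 / 0.336, abs=1e-3)

    def test_pupil_clipping_is_flagged(self, generic_iol, normal_eye_record):
        eye = make_eye(normal_eye_record, generic_iol)
        with pytest.raises(PupilClipError):
            trace_to_retina(eye, Ray(2.2, -5.0, 0.0))

    def test_meridional_symmetry(self, generic_iol, normal_eye_record):
        eye = make_eye(normal_eye_record, generic_iol)
        y_up, _ = trace_to_retina(eye, Ray(0.8, -5.0, 0.01))
        y_dn, _ = trace_to_retina(eye, Ray(-0.8, -5.0, -0.01))
        assert y_dn == -y_up

    def test_snell_invariant_and_reversibility(self, generic_iol,
                                               normal_eye_record):
        """n*sin(theta) is conserved at every interface and a reversed
        exit ray re-traces to the original entry height."""
        eye = make_eye(normal_eye_record, generic_iol)
        ns = [s.n_before for s in eye.surfaces] + \
            [eye.surfaces[-1].n_after]
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(400):
            y0 = rng.uniform(-0.85, 0.85)
            u0 = rng.uniform(-0.04, 0.04)
            ray = Ray(y0, -5.0, u0)
            try:
                states = [ray]
                for i, s in enumerate(eye.surfaces):
                    y, z, ny, nz = intersect_conic(ray, s)
                    ray = Ray(y, z, ray.u, ray.forward)
                    d = np.array([ray.u, 1.0]) / math.hypot(ray.u, 1.0)
                    out = refract_snell(ray, (ny, nz), ns[i], ns[i + 1])
                    dout = np.array([out.u, 1.0]) / math.hypot(out.u, 1.0)
                    n_vec = np.array([ny, nz])
                    sin_in = abs(d[0] * n_vec[1] - d[1] * n_vec[0])
                    sin_out = abs(dout[0] * n_vec[1] - dout[1] * n_vec[0])
                    assert abs(ns[i] * sin_in - ns[i + 1] * sin_out) <= 1e-12
                    ray = out
                    states.append(ray)
            except RayEscapeError:
                continue
            # reverse the exit ray and walk the surfaces backwards
            back = Ray(ray.y, ray.z, ray.u, forward=False)
            for i in range(len(eye.surfaces) - 1, -1, -1):
                y, z, ny, nz = intersect_conic(back, eye.surfaces[i])
                back = Ray(y, z, back.u, back.forward)
                back = refract_snell(back, (ny, nz), ns[i + 1], ns[i])
            assert abs(back.at(-5.0) - y0) <= 1e-9
            checked += 1
        assert checked > 300


class TestBestFocus:
    def test_paraxial_limit_matches_matrix_oracle(self, generic_iol,
                                                  normal_eye_record):
        config = RayTraceConfig(pupil_diameter=0.2)
        eye = make_eye(normal_eye_record, generic_iol, config=config)
        exact = best_focus_refraction(eye, config)
        assert exact == pytest.approx(paraxial_refraction_oracle(eye),
                                      abs=0.05)

    def test_zero_for_eye_focused_at_iso_ray_crossing(self, generic_iol,
                                                      normal_eye_record):
        config = RayTraceConfig()
        eye = make_eye(normal_eye_record, generic_iol, config=config)
        # find where the naked eye's ISO ray crosses the axis, put the
        # retina there: the required correction must vanish
        from scipy.optimize import brentq
        h = 0.5 * config.pupil_diameter * config.focus_ray_fraction

        def pupil_height(y_s):
            _, path = trace_to_retina(eye, Ray(y_s, -5.0, 0.0),
                                      clip_at_pupil=False)
            return path[3][0]

        y_s = brentq(lambda y: pupil_height(y) - h, 0.3 * h, 3 * h,
                     xtol=1e-13)
        _, path = trace_to_retina(eye, Ray(y_s, -5.0, 0.0),
                                  clip_at_pupil=False)
        (y4, z4), (yr, zr) = path[-2], path[-1]
        u = (yr - y4) / (zr - z4)
        crossing = z4 - y4 / u
        focused = EyeModel(eye.surfaces, eye.pupil_z, eye.pupil_diameter,
                           crossing)
        assert best_focus_refraction(focused, config) == pytest.approx(
            0.0, abs=1e-6)

    def test_deterministic_to_microdiopters(self, generic_iol,
                                            normal_eye_record):
        eye = make_eye(normal_eye_record, generic_iol)
        a = best_focus_refraction(eye)
        b = best_focus_refraction(eye)
        assert abs(a - b) < 1e-6

    def test_spherical_aberration_is_positive(self, generic_iol,
                                              normal_eye_record):
        """Marginal rays through a spherical biconvex IOL focus in front
        of paraxial rays (positive longitudinal spherical aberration)."""
        eye = make_eye(normal_eye_record, generic_iol)

        def crossing(y0):
            _, path = trace_to_retina(eye, Ray(y0, -5.0, 0.0),
                                      clip_at_pupil=False)
            (y4, z4), (yr, zr) = path[-2], path[-1]
            u = (yr - y4) / (zr - z4)
            return z4 - y4 / u

        assert crossing(1.8) < crossing(0.05)

    def test_spherical_equivalent_averages_meridians(self, generic_iol,
                                                     normal_eye_record):
        astig = normal_eye_record.model_copy(update={"k1": 42.0, "k2": 44.0})
        geometry = interpolate_geometry(generic_iol, 21.0)
        elp = predict_iol_position(astig, geometry, "auto", ElpConfig(),
                                   generic_iol)
        config = RayTraceConfig()
        se = predict_refraction_raytrace(astig, geometry, elp, config)
        per_meridian = [best_focus_refraction(
            build_pseudophakic_eye(astig, geometry, elp, config, k_d=k),
            config) for k in (42.0, 44.0)]
        assert se == pytest.approx(0.5 * sum(per_meridian), abs=1e-12)


class TestStilesCrawford:
    def test_center_weight_is_one(self):
        assert stiles_crawford_weight(0.0) == 1.0

    def test_hand_value_and_monotonicity(self):
        assert stiles_crawford_weight(2.0, 0.116) == pytest.approx(
            10 ** (-0.464), abs=1e-9)
        ws = [stiles_crawford_weight(y) for y in (0.0, 0.5, 1.0, 2.0, 3.0)]
        assert all(a > b for a, b in zip(ws, ws[1:]))
        assert all(0 < w <= 1 for w in ws)


class TestPowerSolving:
    def test_interpolation_exact_at_keys_linear_in_curvature(self,
                                                             generic_iol):
        g20 = interpolate_geometry(generic_iol, 20.0)
        assert g20 == generic_iol.geometry_table[20.0]
        g205 = interpolate_geometry(generic_iol, 20.5)
        g21 = generic_iol.geometry_table[21.0]
        expect = 0.5 * (1 / g20.r_front + 1 / g21.r_front)
        assert 1 / g205.r_front == pytest.approx(expect, rel=1e-12)

    def test_chosen_power_is_closest_to_target(self, generic_iol,
                                               normal_eye_record):
        res = solve_iol_power_raytrace(normal_eye_record, generic_iol, 0.0)
        for neighbor in (res.chosen_power - 0.5, res.chosen_power + 0.5):
            geometry = interpolate_geometry(generic_iol, neighbor)
            elp = predict_iol_position(normal_eye_record, geometry, "auto",
                                       ElpConfig(), generic_iol)
            se = predict_refraction_raytrace(normal_eye_record, geometry,
                                             elp)
            assert abs(res.predicted_se) <= abs(se) + 1e-9

    def test_longer_eyes_need_less_power(self, generic_iol):
        chosen = []
        for al in (22.0, 24.0, 26.0):
            rec = BiometryRecord(patient_id="S", eye="OD", al=al, acd=3.5,
                                 lt=4.5, cct=540, k1=43.0, k2=43.0)
            chosen.append(solve_iol_power_raytrace(
                rec, generic_iol, 0.0).chosen_power)
        assert chosen[0] > chosen[1] > chosen[2]

    def test_agrees_with_holladay_within_cross_method_band(
            self, generic_iol, normal_eye_record):
        rt = solve_iol_power_raytrace(normal_eye_record, generic_iol, 0.0)
        h1 = calc_formula(normal_eye_record, generic_iol, "holladay1")
        assert abs(rt.emmetropic_power - h1.emmetropic_power) < 1.5

    def test_multiray_mode_close_to_single_ray(self, generic_iol,
                                               normal_eye_record):
        iso = make_eye(normal_eye_record, generic_iol)
        se_iso = best_focus_refraction(iso)
        config = RayTraceConfig(mode="rms_multiray")
        se_rms = best_focus_refraction(iso, config)
        assert se_rms == pytest.approx(se_iso, abs=0.6)
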