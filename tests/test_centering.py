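"""Optical centering: calibration, prelocation, tip alignment, flat-face
fitting and grid generation, all validated against simulator ground truth."""
import math

import numpy as np
import pytest

from loopalign import LoopScene, VirtualBeamline
from loopalign.centering import (
    CenteringResult,
    calibrate_top_cam,
    center_on_tip,
    center_to_flat,
    fit_flat_face,
    grid_from_result,
    prelocate,
)
from loopalign.errors import (
    CalibrationFailure,
    DegenerateFit,
    LoopNotFound,
    NotCentered,
)

from conftest import angle_error_deg, make_config, mount


def sinusoid(c0, amp, w0):
    return lambda w: c0 + amp * math.cos(2 * math.radians(w - w0))


def dense_argmax(fn, step=0.1):
    grid = np.arange(0.0, 180.0, step)
    vals = [fn(w) for w in grid]
    return float(grid[int(np.argmax(vals))])


class TestFitFlatFace:
    def test_recovers_exact_sinusoid(self):
        fn = sinusoid(100.0, 50.0, 30.0)
        samples = [(w, fn(w)) for w in (0.0, 40.0, 80.0, 120.0, 160.0)]
        fit = fit_flat_face(samples)
        assert fit.omega_star == pytest.approx(30.0, abs=1e-6)
        assert angle_error_deg(fit.omega_star, dense_argmax(fn)) <= 0.2

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            c0 = rng.uniform(50, 200)
            amp = rng.uniform(0.1, 0.8) * c0
            w0 = rng.uniform(0, 180)
            fn = sinusoid(c0, amp, w0)
            samples = [(w, fn(w)) for w in (0.0, 40.0, 80.0, 120.0, 160.0)]
            fit = fit_flat_face(samples)
            assert angle_error_deg(fit.omega_star, dense_argmax(fn)) <= 0.2

    def test_constant_area_is_degenerate(self):
        with pytest.raises(DegenerateFit):
            fit_flat_face([(w, 100.0) for w in (0.0, 40.0, 80.0, 120.0, 160.0)])

    def test_too_few_distinct_angles(self):
        with pytest.raises(ValueError):
            fit_flat_face([(0.0, 1.0), (180.0, 1.0), (360.0, 1.0)])

    def test_noise_robustness_monte_carlo(self):
        """1% multiplicative noise: omega_star within 2 deg of truth in at
        least 95 of 100 runs."""
        fn = sinusoid(12000.0, 4000.0, 77.0)
        base = [(w, fn(w)) for w in (0.0, 40.0, 80.0, 120.0, 160.0)]
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            noisy = [(w, a * (1 + 0.01 * rng.standard_normal())) for w, a in base]
            fit = fit_flat_face(noisy)
            hits += angle_error_deg(fit.omega_star, 77.0) <= 2.0
        assert hits >= 95


class TestCalibration:
    def test_unshifted_camera_maps_to_configured_marker(self, exact_bl):
        cal = calibrate_top_cam(exact_bl)
        marker = exact_bl.config.top_camera.beam_marker
        assert abs(cal.top_beam_px[0] - marker[0]) <= 1
        assert abs(cal.top_beam_px[1] - marker[1]) <= 1

    def test_recovers_camera_shift(self, exact_bl):
        """A (7, 2) px drift of the top-camera mount shifts the measured
        beam pixel by exactly that amount."""
        exact_bl.camera_shift_px["top"] = (7.0, 2.0)
        cal = calibrate_top_cam(exact_bl)
        marker = exact_bl.config.top_camera.beam_marker
        assert cal.top_beam_px[0] - marker[0] == pytest.approx(7.0, abs=1)
        assert cal.top_beam_px[1] - marker[1] == pytest.approx(2.0, abs=1)

    def test_unsegmentable_scene_fails(self):
        cfg = make_config(simulator={"foreground_level": 230})  # no contrast
        with pytest.raises(CalibrationFailure):
            calibrate_top_cam(VirtualBeamline(cfg))


class TestPrelocate:
    def test_aligns_tip_at_two_orientations(self, exact_bl):
        mount(exact_bl, tip_offset=(0.8, 0.4, -0.3))
        prelocate(exact_bl)
        marker = exact_bl.config.top_camera.beam_marker
        for w in (0.0, 90.0):
            exact_bl.move_to(omega=w)
            tip = exact_bl.tip_pixel("top")
            assert math.hypot(tip[0] - marker[0], tip[1] - marker[1]) <= 3
        # and the tip is now visible on the narrow microscope field
        from loopalign.vision import segment

        assert segment(exact_bl.render("microscope")).mask.any()

    def test_already_centered_is_noop(self, exact_bl):
        mount(exact_bl, tip_offset=(0.0, 0.0, 0.0))
        prelocate(exact_bl)
        k = exact_bl.config.top_camera.px_per_mm
        assert np.all(np.abs(exact_bl.motors) <= 1.5 / k)

    def test_no_loop_raises(self):
        cfg = make_config(simulator={"foreground_level": 230})
        bl = VirtualBeamline(cfg)
        mount(bl)
        with pytest.raises(LoopNotFound):
            prelocate(bl)


class TestCenterOnTip:
    def test_converges_within_tolerance(self, exact_bl):
        mount(exact_bl, tip_offset=(0.2, -0.3, 0.25))
        center_on_tip(exact_bl)
        marker = exact_bl.config.microscope_camera.beam_marker
        for w in (0.0, 90.0):
            exact_bl.move_to(omega=w)
            tip = exact_bl.tip_pixel("microscope")
            assert math.hypot(tip[0] - marker[0], tip[1] - marker[1]) <= 2.5

    def test_restores_entry_omega(self, exact_bl):
        mount(exact_bl, tip_offset=(0.1, 0.1, 0.0))
        exact_bl.move_to(omega=42.0)
        center_on_tip(exact_bl)
        assert exact_bl.state.omega == pytest.approx(42.0)

    def test_idempotent(self, exact_bl):
        mount(exact_bl, tip_offset=(0.3, 0.2, -0.2))
        center_on_tip(exact_bl)
        before = exact_bl.motors
        center_on_tip(exact_bl)
        k = exact_bl.config.microscope_camera.px_per_mm
        tol = exact_bl.config.centering.tip_tolerance_px / k
        assert np.all(np.abs(exact_bl.motors - before) < tol)

    def test_tip_outside_field_raises(self, exact_bl):
        mount(exact_bl, tip_offset=(0.0, 2.0, 0.0))  # 400 px above the frame
        with pytest.raises(LoopNotFound):
            center_on_tip(exact_bl)


class TestCenterToFlat:
    def test_recovers_flat_face_and_bbox(self, exact_bl):
        scene = mount(exact_bl, flat_face_omega=62.0, tip_offset=(0.15, 0.2, -0.1))
        prelocate(exact_bl)
        res = center_to_flat(exact_bl)
        assert res.status == "centered"
        assert angle_error_deg(res.flat_face_omega, 62.0) <= 2.0
        k = exact_bl.config.microscope_camera.px_per_mm
        assert res.thickness_px == pytest.approx(scene.loop_thickness * k, abs=3)
        # bbox overlap with the analytic loop ellipse box at the flat face
        exact_bl.move_to(omega=res.flat_face_omega)
        ec, Ap = exact_bl._ellipsoid_projection("microscope")
        ext = np.sqrt(np.diag(np.linalg.inv(Ap)))
        px, py = exact_bl.lab_to_pixel(np.array([ec[0], ec[1], 0.0]), "microscope")
        ax1, ax2 = px - ext[0] * k, px + ext[0] * k
        ay1, ay2 = py - ext[1] * k, py + ext[1] * k
        (bx1, by1), (bx2, by2) = res.bbox
        ix = max(0, min(ax2, bx2) - max(ax1, bx1))
        iy = max(0, min(ay2, by2) - max(ay1, by1))
        inter = ix * iy
        union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
        assert inter / union >= 0.8

    def test_beamline_left_at_flat_face(self, exact_bl):
        mount(exact_bl, flat_face_omega=100.0, tip_offset=(0.1, 0.0, 0.1))
        res = center_to_flat(exact_bl)
        assert exact_bl.state.omega % 180.0 == pytest.approx(res.flat_face_omega, abs=1e-9)

    def test_no_centering_option_disables_motion(self, exact_bl):
        mount(exact_bl, tip_offset=(0.3, 0.2, 0.1))
        res = center_to_flat(exact_bl, no_centering=True)
        assert res.status == "disabled"
        assert np.all(exact_bl.motors == 0.0)

    def test_loop_free_scene_not_found(self):
        cfg = make_config(simulator={"foreground_level": 230})
        bl = VirtualBeamline(cfg)
        mount(bl)
        assert center_to_flat(bl).status == "not_found"

    def test_near_spherical_sample_degrades_gracefully(self, exact_bl):
        """A sample with almost no area modulation yields a degenerate fit
        and falls back to the entry omega, still marked centered."""
        mount(
            exact_bl,
            scene=LoopScene(
                loop_semi_axis_a=0.2, loop_semi_axis_b=0.2, loop_thickness=0.39,
                flat_face_omega=0.0,
            ),
        )
        exact_bl.move_to(omega=15.0)
        res = center_to_flat(exact_bl)
        assert res.status == "centered"
        assert res.degenerate_fit
        assert res.flat_face_omega == pytest.approx(15.0)


class TestGridFromResult:
    def _result(self, w_px, h_px, omega=0.0):
        return CenteringResult(
            status="centered",
            tip_motor=(0.0, 0.0, 0.0),
            flat_face_omega=omega,
            thickness_px=30,
            bbox=((100, 100), (100 + w_px - 1, 100 + h_px - 1)),
        )

    def test_exact_grid_arithmetic(self, exact_bl):
        # 0.30 x 0.20 mm bbox at 200 px/mm, 0.10 mm beam -> 3 x 2 grid
        plan = grid_from_result(exact_bl, self._result(60, 40), beam_size_mm=0.10)
        assert plan.shape == (2, 3)
        xs = [t["x"] for t in plan.targets[0]]
        assert np.allclose(np.diff(xs), -0.10)  # motor step of one beam size

    def test_ceil_rule_and_symmetric_overlap(self, exact_bl):
        # 0.25 mm wide -> ceil(2.5) = 3 columns, centered on the bbox
        plan = grid_from_result(exact_bl, self._result(50, 40), beam_size_mm=0.10)
        assert plan.ncols == 3
        rect_centers = [r[0] + r[2] / 2.0 for r in plan.pixel_rects[0]]
        bbox_cx = (100 + 149) / 2.0
        assert np.mean(rect_centers) == pytest.approx(bbox_cx)

    def test_full_coverage_within_half_beam(self, exact_bl):
        rng = np.random.default_rng(3)
        k = exact_bl.config.microscope_camera.px_per_mm
        for _ in range(20):
            w, h = rng.integers(10, 200), rng.integers(10, 150)
            beam = rng.uniform(0.03, 0.12)
            plan = grid_from_result(exact_bl, self._result(int(w), int(h)), beam_size_mm=beam)
            assert plan.ncols == math.ceil((w / k) / beam)
            assert plan.nrows == math.ceil((h / k) / beam)
            cols = np.array([r[0] + r[2] / 2 for r in plan.pixel_rects[0]])
            rows = np.array([plan.pixel_rects[i][0][1] + plan.pixel_rects[i][0][3] / 2
                             for i in range(plan.nrows)])
            for x in np.linspace(100, 100 + w - 1, 33):
                assert np.min(np.abs(cols - x)) <= beam * k / 2 + 0.5
            for y in np.linspace(100, 100 + h - 1, 33):
                assert np.min(np.abs(rows - y)) <= beam * k / 2 + 0.5

    def test_serpentine_order(self, exact_bl):
        plan = grid_from_result(exact_bl, self._result(60, 40), beam_size_mm=0.10)
        assert plan.order == [(0, 0), (0, 1), (0, 2), (1, 2), (1, 1), (1, 0)]

    def test_requires_centered_status(self, exact_bl):
        with pytest.raises(NotCentered):
            grid_from_result(exact_bl, CenteringResult(status="not_found"))
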