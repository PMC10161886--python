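"""Automatic loop centering (ALC) procedures.

The pipeline mirrors routine MX beamline practice:

1. ``calibrate_top_cam`` — map the beam position onto the wide-field top
   camera using a reference loop centered on the microscope beam marker.
2. ``prelocate`` — coarse alignment on the top camera at two orthogonal
   omega values, guaranteeing the tip enters the narrow microscope field of
   view and its focus band.
3. ``center_on_tip`` — align the loop tip to the microscope beam marker at
   omega and omega+90, which puts the tip on the rotation axis at the beam.
4. ``center_to_flat`` — the full optical centering: tip centering, a 180 deg
   projected-area sweep fitted with a 2-omega sinusoid (``fit_flat_face``) to
   find the flat-face angle, a 90 deg-away thickness measurement, a final tip
   centering, and the flat-face bounding box.
5. ``grid_from_result`` — convert the bounding box into a serpentine raster
   of motor targets at one beam-size spacing.

A planar loop's projected area is 180 deg periodic in omega, so the area
model is ``area(w) = c0 + c1 cos 2w + c2 sin 2w`` and the flat face sits at
``w* = atan2(c2, c1) / 2``.
"""
from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import vision
from .errors import (
    CalibrationFailure,
    ConvergenceFailure,
    DegenerateFit,
    LoopNotFound,
    NotCentered,
)
from .virtual_beamline import LoopScene, VirtualBeamline, rot_x


@dataclass
class CalibrationMap:
    """Beam-marker pixel on the top camera, as measured (not configured)."""

    top_beam_px: Tuple[float, float]
    timestamp: float


@dataclass
class SinusoidFit:
    c0: float
    c1: float
    c2: float
    residual: float
    omega_star: float  # degrees in [0, 180)


@dataclass
class CenteringResult:
    status: str                       # centered | not_found | disabled
    tip_motor: Optional[Tuple[float, float, float]] = None
    flat_face_omega: Optional[float] = None
    thickness_px: Optional[int] = None
    bbox: Optional[Tuple[Tuple[int, int], Tuple[int, int]]] = None
    degenerate_fit: bool = False


@dataclass
class GridPlan:
    """Raster-scan geometry: motor targets indexed [row][col], plus the pixel
    rectangle of every box on the source camera for overlay rendering."""

    omega: float
    nrows: int
    ncols: int
    targets: List[List[dict]]
    order: List[Tuple[int, int]]      # serpentine visiting order
    pixel_rects: List[List[Tuple[float, float, float, float]]]  # x, y, w, h
    beam_size_mm: float
    camera: str

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.nrows, self.ncols)

    def ordered_targets(self) -> List[dict]:
        return [self.targets[r][c] for r, c in self.order]


def _norm_omega(w: float) -> float:
    return w % 360.0


def _roi_depth_px(bl: VirtualBeamline, camera: str) -> float:
    v = bl.config.vision
    return v.roi_factor * v.expected_loop_diameter_mm * bl.config.camera(camera).px_per_mm


def _measure_tip(bl: VirtualBeamline, camera: str) -> Tuple[float, float]:
    cam = bl.config.camera(camera)
    frame = bl.render(camera)
    sil = vision.segment(frame, bl.config.vision.min_component_area)
    return vision.find_tip(sil, cam.tip_direction)


def _move_tip_to(bl: VirtualBeamline, camera: str, marker: Tuple[float, float]) -> float:
    """One measure-and-move iteration; returns the pre-move pixel residual."""
    cam = bl.config.camera(camera)
    tip = _measure_tip(bl, camera)
    ex, ey = tip[0] - marker[0], tip[1] - marker[1]
    resid = math.hypot(ex, ey)
    k = cam.px_per_mm
    (i0, i1), _, ysign = bl._image_axes(cam)
    dlab = np.zeros(3)
    dlab[i0] = -ex / k
    dlab[i1] = -ey / (ysign * k)
    dm = rot_x(bl.state.omega).T @ dlab
    bl.move_to(x=dm[0], y=dm[1], z=dm[2], relative=True)
    return resid


def calibrate_top_cam(
    bl: VirtualBeamline,
    rng: Optional[np.random.Generator] = None,
) -> CalibrationMap:
    """Measure where the beam position falls on the top camera.

    A reference loop is mounted and centered on the microscope beam marker
    (the microscope is the trusted reference); the tip pixel seen by the top
    camera is then, by construction, the beam position on that camera.  The
    procedure is fully automated and survives top-camera mount drift.
    """
    rng = rng or np.random.default_rng(0)
    held = bl.scene
    if held is not None:
        bl.dismount()
    marker_scene = LoopScene(
        loop_semi_axis_a=0.15, loop_semi_axis_b=0.15, loop_thickness=0.10,
        flat_face_omega=0.0, background_spots=0,
    )
    try:
        bl.mount_sample(marker_scene, rng)
        try:
            center_on_tip(bl)
            tip = _measure_tip(bl, "top")
        except (LoopNotFound, ConvergenceFailure) as exc:
            raise CalibrationFailure(f"reference loop not segmentable: {exc}") from exc
    finally:
        bl.dismount()
    return CalibrationMap(top_beam_px=tip, timestamp=time.time())


def prelocate(
    bl: VirtualBeamline,
    calibration: Optional[CalibrationMap] = None,
    tolerance_px: float = 3.0,
    rounds: int = 3,
) -> str:
    """Coarse tip alignment on the wide-field top camera.

    The tip is driven to the top-camera beam pixel at the entry omega and at
    omega+90, which bounds both the in-plane offset and the depth offset so
    the sample enters the microscope field of view and focus band.
    """
    marker = calibration.top_beam_px if calibration else bl.config.top_camera.beam_marker
    entry = bl.state.omega
    try:
        for _ in range(rounds):
            worst = 0.0
            for wo in (entry, entry + 90.0):
                bl.move_to(omega=_norm_omega(wo))
                worst = max(worst, _move_tip_to(bl, "top", marker))
            if worst <= tolerance_px:
                break
    finally:
        bl.move_to(omega=_norm_omega(entry))
    return "prelocated"


def center_on_tip(
    bl: VirtualBeamline,
    tolerance_px: Optional[float] = None,
    rounds: Optional[int] = None,
) -> Tuple[float, float, float]:
    """Align the loop tip to the microscope beam marker at omega and
    omega+90, leaving omega at its entry value.

    Returns the final motor positions.  Raises :class:`ConvergenceFailure`
    when the residual exceeds tolerance after the refinement rounds, and
    :class:`LoopNotFound` when the tip is outside the field of view.
    """
    cfg = bl.config.centering
    tol = cfg.tip_tolerance_px if tolerance_px is None else tolerance_px
    rounds = cfg.max_refine_rounds if rounds is None else rounds
    marker = bl.config.microscope_camera.beam_marker
    entry = bl.state.omega
    try:
        converged = False
        for _ in range(rounds):
            worst = 0.0
            for wo in (entry, entry + 90.0):
                bl.move_to(omega=_norm_omega(wo))
                worst = max(worst, _move_tip_to(bl, "microscope", marker))
            if worst <= tol:
                converged = True
                break
        if not converged:
            # verification pass: residuals after the last correction
            worst = 0.0
            for wo in (entry, entry + 90.0):
                bl.move_to(omega=_norm_omega(wo))
                tip = _measure_tip(bl, "microscope")
                worst = max(worst, math.hypot(tip[0] - marker[0], tip[1] - marker[1]))
            if worst > tol:
                raise ConvergenceFailure(
                    f"tip residual {worst:.2f} px above tolerance {tol} px"
                )
    finally:
        bl.move_to(omega=_norm_omega(entry))
    return (bl.state.x, bl.state.y, bl.state.z)


def fit_flat_face(
    samples: Sequence[Tuple[float, float]],
    degenerate_fraction: float = 0.02,
) -> SinusoidFit:
    """Least-squares fit of ``area(w) = c0 + c1 cos 2w + c2 sin 2w``.

    ``omega_star`` maximizes the fitted area.  Raises :class:`DegenerateFit`
    when the modulation amplitude is below ``degenerate_fraction`` of the
    mean area (near-spherical sample: no defined flat face).
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 (omega, area) samples")
    w = np.array([s[0] for s in samples], dtype=float)
    a = np.array([s[1] for s in samples], dtype=float)
    if np.unique(np.round(w % 180.0, 6)).size < 3:
        raise ValueError("need samples at >= 3 distinct omega values mod 180")
    wr = np.deg2rad(w)
    X = np.column_stack([np.ones_like(wr), np.cos(2 * wr), np.sin(2 * wr)])
    coef, *_ = np.linalg.lstsq(X, a, rcond=None)
    c0, c1, c2 = (float(v) for v in coef)
    residual = float(np.linalg.norm(X @ coef - a))
    amplitude = math.hypot(c1, c2)
    if amplitude < degenerate_fraction * max(abs(c0), 1e-12):
        raise DegenerateFit(
            f"area modulation {amplitude:.3g} below {degenerate_fraction} of mean {c0:.3g}"
        )
    omega_star = (0.5 * math.degrees(math.atan2(c2, c1))) % 180.0
    return SinusoidFit(c0=c0, c1=c1, c2=c2, residual=residual, omega_star=omega_star)


def center_to_flat(
    bl: VirtualBeamline,
    no_centering: bool = False,
    rng: Optional[np.random.Generator] = None,
    trace_dir=None,
) -> CenteringResult:
    """Full optical centering.

    Sequence: tip centering; projected-area sweep at entry + {0, 40, 80,
    120, 160} deg; sinusoid fit for the flat-face angle; thickness at
    omega*+90; tip centering again; bounding box at omega*.  The beamline is
    left at the flat-face omega.  A degenerate fit downgrades gracefully to
    the entry omega with the result still marked centered.
    """
    if no_centering:
        return CenteringResult(status="disabled")
    cfg = bl.config.centering
    cam = bl.config.microscope_camera
    roi = _roi_depth_px(bl, "microscope")
    trace: List[dict] = []

    try:
        center_on_tip(bl)
    except LoopNotFound:
        return CenteringResult(status="not_found")

    entry = bl.state.omega
    step = cfg.sweep_step_deg
    nsteps = int(round(180.0 / step))
    samples: List[Tuple[float, float]] = []
    for i in range(nsteps):
        w = _norm_omega(entry + i * step)
        bl.move_to(omega=w)
        frame = bl.render("microscope")
        sil = vision.segment(frame, bl.config.vision.min_component_area)
        area = float(vision.projected_area(sil, cam.tip_direction, roi))
        if rng is not None and cfg.area_noise_sigma > 0:
            area *= 1.0 + cfg.area_noise_sigma * rng.standard_normal()
        samples.append((w, area))
        trace.append({"step": "sweep", "omega": w, "area": area})
        if trace_dir is not None:
            frame.save_png(f"{trace_dir}/sweep_{i}.png")

    degenerate = False
    try:
        fit = fit_flat_face(samples, cfg.degenerate_fraction)
        omega_star = fit.omega_star
    except DegenerateFit:
        degenerate = True
        omega_star = entry % 180.0
    trace.append({"step": "fit", "omega_star": omega_star, "degenerate": degenerate})

    bl.move_to(omega=_norm_omega(omega_star + 90.0))
    frame = bl.render("microscope")
    sil = vision.segment(frame, bl.config.vision.min_component_area)
    thickness = vision.vertical_extent(sil, cam.tip_direction, roi)

    center_on_tip(bl)

    bl.move_to(omega=_norm_omega(omega_star))
    frame = bl.render("microscope")
    sil = vision.segment(frame, bl.config.vision.min_component_area)
    bbox = vision.bounding_box(sil, cam.tip_direction, roi)
    if trace_dir is not None:
        frame.save_png(f"{trace_dir}/flat_face.png")
        with open(f"{trace_dir}/trace.json", "w", encoding="utf-8") as fh:
            json.dump(trace, fh, indent=2, sort_keys=True)

    return CenteringResult(
        status="centered",
        tip_motor=(bl.state.x, bl.state.y, bl.state.z),
        flat_face_omega=omega_star % 180.0,
        thickness_px=int(thickness),
        bbox=bbox,
        degenerate_fit=degenerate,
    )


def grid_from_result(
    bl: VirtualBeamline,
    result: CenteringResult,
    beam_size_mm: Optional[float] = None,
    camera: str = "microscope",
) -> GridPlan:
    """Raster of motor targets covering the bounding box at the flat-face
    omega: one beam size per step, ceil(extent / step) boxes per axis,
    centered on the bbox center, serpentine order starting top-left.

    The vertical span covers the full bounding box, not the measured loop
    thickness — sample settling between optical and diffraction centering
    makes a thickness-restricted scan unreliable.
    """
    if result.status != "centered":
        raise NotCentered(f"centering status is {result.status!r}")
    beam = bl.config.grid.beam_size_mm if beam_size_mm is None else beam_size_mm
    cam = bl.config.camera(camera)
    k = cam.px_per_mm
    (x1, y1), (x2, y2) = result.bbox
    w_mm = (x2 - x1 + 1) / k
    h_mm = (y2 - y1 + 1) / k
    ncols = max(1, math.ceil(w_mm / beam))
    nrows = max(1, math.ceil(h_mm / beam))
    cx, cy = (x1 + x2) / 2.0, (y1 + y2) / 2.0
    omega = _norm_omega(result.flat_face_omega)
    bx, by = cam.beam_marker
    (i0, i1), _, ysign = bl._image_axes(cam)
    Rt = rot_x(omega).T
    cur = bl.motors
    step_px = beam * k

    targets: List[List[dict]] = []
    rects: List[List[Tuple[float, float, float, float]]] = []
    for r in range(nrows):
        row_t, row_r = [], []
        gy = cy + (r - (nrows - 1) / 2.0) * step_px
        for c in range(ncols):
            gx = cx + (c - (ncols - 1) / 2.0) * step_px
            dlab = np.zeros(3)
            dlab[i0] = (bx - gx) / k
            dlab[i1] = (by - gy) / (ysign * k)
            dm = Rt @ dlab
            row_t.append({
                "x": float(cur[0] + dm[0]),
                "y": float(cur[1] + dm[1]),
                "z": float(cur[2] + dm[2]),
                "omega": omega,
            })
            row_r.append((gx - step_px / 2.0, gy - step_px / 2.0, step_px, step_px))
        targets.append(row_t)
        rects.append(row_r)

    order = [
        (r, c if r % 2 == 0 else ncols - 1 - c)
        for r in range(nrows)
        for c in range(ncols)
    ]
    return GridPlan(
        omega=omega, nrows=nrows, ncols=ncols, targets=targets,
        order=order, pixel_rects=rects, beam_size_mm=beam, camera=camera,
    )
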