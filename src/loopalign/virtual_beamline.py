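"""Virtual MX beamline: a deterministic stand-in for all hardware.

The simulator owns a parametric ground-truth sample (:class:`LoopScene`),
motor state, and two cameras, and can

* render silhouette frames of the mounted sample at any motor state,
* execute motor moves against soft limits,
* synthesize per-position diffraction spot counts for grid scans.

Geometry conventions
--------------------
Lab frame: ``x`` along the omega rotation axis (horizontal), ``y`` vertical
(up positive), ``z`` along the beam at omega = 0.  The beam crosses the
rotation axis at the lab origin.  Omega rotates the sample about ``x``.

The centering motors ride on the rotation stage, so a material point ``p``
of the sample (scene frame, relative to the rotation axis at omega = 0)
sits at ``lab = R_x(omega) @ (p + m)`` where ``m = (x, y, z)`` is the motor
vector.  Bringing the loop tip onto the rotation axis *and* the beam means
driving ``tip + m`` to zero.

Images: origin top-left, x right, y down.  Moving the sample +1 mm in lab y
moves its silhouette *up* (-px_per_mm pixels in image y).  The microscope
looks along the beam (+z) and images lab (x, y); the top camera looks down
(-y) and images lab (x, z), with +z mapping to +image-y.

The loop is modeled as an oblate ellipsoid: semi-axes ``a`` (along the pin),
``b`` (in the loop plane) and ``thickness/2`` (normal to the loop plane).
Its projected area is then exactly 180 deg periodic in omega and maximal at
the flat-face angle, while the edge-on projected height equals the loop
thickness — the two facts the centering procedures rely on.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image
from pydantic import BaseModel, Field, model_validator

from .config import BeamlineConfig, CameraGeometry, default_config
from .errors import LoopAlignError, MotorLimit, MountFailure, NoSampleMounted


def rot_x(deg: float) -> np.ndarray:
    """Rotation matrix about the lab x axis (the omega axis)."""
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


class LoopScene(BaseModel):
    """Ground-truth parametric sample: pin, planar elliptical loop, optional
    embedded crystal.

    All lengths in mm, angles in degrees.  ``tip_offset`` is the loop tip
    position relative to the rotation axis at omega = 0 before any mount
    error.  ``crystal_center`` is (u, v) in loop-plane coordinates relative
    to the tip: u along the pin axis (negative = into the loop), v in-plane
    perpendicular.
    """

    pin_length: float = Field(default=2.0, gt=0)
    pin_radius: float = Field(default=0.05, gt=0)
    loop_semi_axis_a: float = Field(default=0.40, gt=0)
    loop_semi_axis_b: float = Field(default=0.25, gt=0)
    flat_face_omega: float = Field(default=60.0, ge=0, lt=180)
    tip_offset: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    loop_thickness: float = Field(default=0.20, gt=0)
    crystal_center: Optional[Tuple[float, float]] = None
    crystal_sigma: float = Field(default=0.05, gt=0)
    crystal_peak_spots: int = Field(default=100, ge=0)
    background_spots: int = Field(default=0, ge=0)
    ice_jitter_sigma: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _invariants(self) -> "LoopScene":
        a, b = self.loop_semi_axis_a, self.loop_semi_axis_b
        if a < b:
            raise ValueError("loop semi-axes must satisfy a >= b")
        if self.loop_thickness >= 2 * b:
            raise ValueError("loop_thickness must be < 2*b")
        if self.crystal_center is not None:
            u, v = self.crystal_center
            if ((u + a) / a) ** 2 + (v / b) ** 2 > 1.0 + 1e-9:
                raise ValueError("crystal_center must lie inside the loop ellipse")
        return self

    # loop-plane unit vectors in the scene frame (omega = 0)
    def plane_vectors(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = rot_x(-self.flat_face_omega) @ np.array([0.0, 1.0, 0.0])
        e3 = np.cross(e1, e2)
        return e1, e2, e3

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LoopScene":
        return cls.model_validate(json.loads(text))


def random_scene(
    rng: np.random.Generator,
    with_crystal: bool = True,
    tip_offset_range_mm: float = 0.3,
    background_spots: int = 2,
    crystal_peak_spots: int = 100,
    crystal_sigma: float = 0.05,
    ice_jitter_sigma: float = 0.0,
) -> LoopScene:
    """Draw a randomized but physically plausible scene.

    Loop sizes span typical nylon loops (0.3-0.45 mm semi-axes), the flat
    face angle is uniform over [0, 180) and the crystal, when present, sits
    near the loop center well inside the ellipse.
    """
    a = float(rng.uniform(0.30, 0.45))
    b = float(rng.uniform(0.18, 0.28))
    thickness = float(rng.uniform(0.6, 0.9) * b)
    crystal = None
    if with_crystal:
        u = float(-a + rng.uniform(-0.3, 0.3) * a)
        v = float(rng.uniform(-0.4, 0.4) * b)
        crystal = (u, v)
    return LoopScene(
        loop_semi_axis_a=a,
        loop_semi_axis_b=b,
        loop_thickness=thickness,
        flat_face_omega=float(rng.uniform(0.0, 180.0)),
        tip_offset=tuple(rng.uniform(-tip_offset_range_mm, tip_offset_range_mm, 3)),
        crystal_center=crystal,
        crystal_sigma=crystal_sigma,
        crystal_peak_spots=crystal_peak_spots,
        background_spots=background_spots,
        ice_jitter_sigma=ice_jitter_sigma,
    )


@dataclass
class BeamlineState:
    """Snapshot of the virtual motor positions and machine mode."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    omega: float = 0.0
    chi: float = 0.0
    phi: float = 0.0
    mode: str = "idle"  # idle | sample_exchange | alignment | acquiring
    sample_mounted: bool = False


@dataclass
class Frame:
    """One grayscale camera frame (uint8, dark sample on light background)."""

    camera: str
    pixels: np.ndarray
    omega_at_capture: float

    def save_png(self, path) -> None:
        Image.fromarray(self.pixels, mode="L").save(path, format="PNG")

    @classmethod
    def load_png(cls, path, camera: str = "microscope", omega: float = 0.0) -> "Frame":
        arr = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
        return cls(camera=camera, pixels=arr, omega_at_capture=omega)


class VirtualBeamline:
    """In-process beamline simulator.

    Rendering is a pure function of (scene, motor state, camera): identical
    inputs give bit-identical frames.  All randomness (mount error, ice
    jitter, Poisson spot counts, simulated faults) flows through explicit
    generators supplied by the caller.
    """

    def __init__(self, config: Optional[BeamlineConfig] = None):
        self.config = config or default_config()
        self.state = BeamlineState()
        self.scene: Optional[LoopScene] = None
        self._mount_error = np.zeros(3)
        self._ice_jitter = np.zeros(3)
        self._ice_applied = False
        # simulated per-camera mount drift of the optics, in pixels
        self.camera_shift_px = {"top": (0.0, 0.0), "microscope": (0.0, 0.0)}

    # ------------------------------------------------------------------ admin

    def mount_sample(self, scene: LoopScene, rng: np.random.Generator) -> BeamlineState:
        if self.state.mode not in ("idle", "sample_exchange"):
            raise LoopAlignError(f"cannot mount in mode {self.state.mode!r}")
        if rng.random() < self.config.simulator.mount_failure_prob:
            raise MountFailure("simulated robot mount failure")
        cap = self.config.simulator.mount_capture_range_mm
        self.scene = scene
        self._mount_error = rng.uniform(-cap, cap, 3)
        self._ice_jitter = np.zeros(3)
        self._ice_applied = False
        self.state = BeamlineState(mode="alignment", sample_mounted=True)
        return self.state

    def dismount(self) -> None:
        self.scene = None
        self.state = BeamlineState(mode="idle", sample_mounted=False)

    def apply_ice_jitter(self, rng: np.random.Generator) -> np.ndarray:
        """Displace the sample once, emulating settling of an icy pin base
        between optical centering and the diffraction scan.  Subsequent
        calls are no-ops until the next mount."""
        self._require_sample()
        if not self._ice_applied:
            sigma = self.scene.ice_jitter_sigma
            self._ice_jitter = sigma * rng.standard_normal(3)
            self._ice_applied = True
        return self._ice_jitter.copy()

    def _require_sample(self) -> None:
        if self.scene is None:
            raise NoSampleMounted("no sample on the goniometer")

    # ------------------------------------------------------------------ motion

    def move_to(
        self,
        x: Optional[float] = None,
        y: Optional[float] = None,
        z: Optional[float] = None,
        omega: Optional[float] = None,
        chi: Optional[float] = None,
        phi: Optional[float] = None,
        relative: bool = False,
    ) -> BeamlineState:
        s = self.state
        lim = self.config.limits

        def tgt(cur, req):
            if req is None:
                return cur
            return cur + req if relative else req

        nx, ny, nz = tgt(s.x, x), tgt(s.y, y), tgt(s.z, z)
        nomega, nchi, nphi = tgt(s.omega, omega), tgt(s.chi, chi), tgt(s.phi, phi)
        t = lim.translation_mm
        for name, val, (lo, hi) in [
            ("x", nx, (-t, t)), ("y", ny, (-t, t)), ("z", nz, (-t, t)),
            ("omega", nomega, lim.omega_deg),
            ("chi", nchi, lim.chi_deg),
            ("phi", nphi, lim.phi_deg),
        ]:
            if not (lo <= val <= hi):
                raise MotorLimit(f"{name} target {val:.4g} outside soft limits [{lo}, {hi}]")
        s.x, s.y, s.z, s.omega, s.chi, s.phi = nx, ny, nz, nomega, nchi, nphi
        return s

    @property
    def motors(self) -> np.ndarray:
        return np.array([self.state.x, self.state.y, self.state.z])

    # ------------------------------------------------------------- lab geometry

    def _tip_scene(self) -> np.ndarray:
        """Tip position in the scene frame including mount error and ice jitter."""
        return np.asarray(self.scene.tip_offset) + self._mount_error + self._ice_jitter

    def tip_lab(self, motors: Optional[np.ndarray] = None, omega: Optional[float] = None) -> np.ndarray:
        self._require_sample()
        m = self.motors if motors is None else np.asarray(motors, dtype=float)
        w = self.state.omega if omega is None else omega
        return rot_x(w) @ (self._tip_scene() + m)

    def crystal_lab(self, motors: Optional[np.ndarray] = None, omega: Optional[float] = None) -> np.ndarray:
        """Lab position of the crystal center at the given motor state."""
        self._require_sample()
        if self.scene.crystal_center is None:
            raise LoopAlignError("scene has no crystal")
        m = self.motors if motors is None else np.asarray(motors, dtype=float)
        w = self.state.omega if omega is None else omega
        e1, e2, _ = self.scene.plane_vectors()
        u, v = self.scene.crystal_center
        p = self._tip_scene() + u * e1 + v * e2
        return rot_x(w) @ (p + m)

    # --------------------------------------------------------------- projection

    @staticmethod
    def _image_axes(cam: CameraGeometry) -> Tuple[Tuple[int, int], int, float]:
        """(image coordinate indices in lab space, depth index, sign of lab
        coordinate per image-y step)."""
        if cam.view_axis == "horizontal":   # microscope: images lab (x, y)
            return (0, 1), 2, -1.0          # image y down = -lab y
        return (0, 2), 1, +1.0              # top camera: images lab (x, z)

    def lab_to_pixel(self, point_lab: np.ndarray, camera: str) -> Tuple[float, float]:
        cam = self.config.camera(camera)
        (i0, i1), _, ysign = self._image_axes(cam)
        dx, dy = self.camera_shift_px[camera]
        bx, by = cam.beam_marker
        px = bx + dx + cam.px_per_mm * point_lab[i0]
        py = by + dy + ysign * cam.px_per_mm * point_lab[i1]
        return (px, py)

    def tip_pixel(self, camera: str) -> Tuple[float, float]:
        """Analytic projection of the ground-truth tip onto a camera."""
        return self.lab_to_pixel(self.tip_lab(), camera)

    def _ellipsoid_projection(self, camera: str) -> Tuple[np.ndarray, np.ndarray]:
        """Projected loop outline: returns (center in image-plane lab coords,
        2x2 quadric A') such that a point p is inside iff
        (p-c)^T A' (p-c) <= 1."""
        cam = self.config.camera(camera)
        (i0, i1), idep, _ = self._image_axes(cam)
        sc = self.scene
        R = rot_x(self.state.omega)
        e1, e2, e3 = sc.plane_vectors()
        axes = [R @ e1, R @ e2, R @ e3]
        semis = [sc.loop_semi_axis_a, sc.loop_semi_axis_b, sc.loop_thickness / 2.0]
        M = sum(np.outer(u, u) / s**2 for u, s in zip(axes, semis))
        center = R @ (self._tip_scene() - sc.loop_semi_axis_a * e1 + self.motors)
        img = [i0, i1]
        A = M[np.ix_(img, img)]
        bv = M[np.ix_(img, [idep])][:, 0]
        c = M[idep, idep]
        Ap = A - np.outer(bv, bv) / c
        return center[img], Ap

    def analytic_loop_area_px(self, camera: str) -> float:
        """Exact projected loop-silhouette area in pixels (ellipse area of the
        projected ellipsoid) — ground truth for vision tests."""
        self._require_sample()
        _, Ap = self._ellipsoid_projection(camera)
        area_mm2 = math.pi / math.sqrt(np.linalg.det(Ap))
        return area_mm2 * self.config.camera(camera).px_per_mm ** 2

    # ---------------------------------------------------------------- rendering

    def render(self, camera: str) -> Frame:
        self._require_sample()
        cam = self.config.camera(camera)
        simcfg = self.config.simulator
        H, W = cam.image_height, cam.image_width
        pixels = np.full((H, W), simcfg.background_level, dtype=np.uint8)

        k = cam.px_per_mm
        (i0, i1), idep, ysign = self._image_axes(cam)
        dxpix, dypix = self.camera_shift_px[camera]
        bx, by = cam.beam_marker

        # loop ellipse in image-plane lab coords
        ec, Ap = self._ellipsoid_projection(camera)
        Ainv = np.linalg.inv(Ap)
        ext = np.sqrt(np.maximum(np.diag(Ainv), 0.0))  # half extents (mm)

        # pin: axis along lab x, circular cross-section
        sc = self.scene
        tip = self._tip_scene() + self.motors
        yz = rot_x(self.state.omega) @ np.array([0.0, tip[1], tip[2]])
        pin_c = {0: tip[0], 1: yz[1], 2: yz[2]}
        pin_x_hi = tip[0] - 2 * sc.loop_semi_axis_a
        pin_x_lo = pin_x_hi - sc.pin_length

        def to_px_u(lab):  # lab image-axis-0 coordinate -> pixel x
            return bx + dxpix + k * lab

        def to_px_v(lab):  # lab image-axis-1 coordinate -> pixel y
            return by + dypix + ysign * k * lab

        # pixel-space bounding rect of both primitives
        us = [to_px_u(ec[0] - ext[0]), to_px_u(ec[0] + ext[0]),
              to_px_u(pin_x_lo), to_px_u(pin_x_hi)]
        vs = [to_px_v(ec[1] - ext[1]), to_px_v(ec[1] + ext[1]),
              to_px_v(pin_c[i1] - sc.pin_radius), to_px_v(pin_c[i1] + sc.pin_radius)]
        c0 = max(0, int(math.floor(min(us))) - 2)
        c1 = min(W, int(math.ceil(max(us))) + 3)
        r0 = max(0, int(math.floor(min(vs))) - 2)
        r1 = min(H, int(math.ceil(max(vs))) + 3)
        if c1 <= c0 or r1 <= r0:
            return Frame(camera=camera, pixels=pixels, omega_at_capture=self.state.omega)

        s = max(1, simcfg.supersample)
        # sub-pixel sample centers, converted back to image-plane lab coords
        uu = c0 + (np.arange((c1 - c0) * s) + 0.5) / s - 0.5
        vv = r0 + (np.arange((r1 - r0) * s) + 0.5) / s - 0.5
        lab_u = (uu - bx - dxpix) / k
        lab_v = (vv - by - dypix) / (ysign * k)
        U, V = np.meshgrid(lab_u, lab_v)

        du, dv = U - ec[0], V - ec[1]
        q = Ap[0, 0] * du * du + 2 * Ap[0, 1] * du * dv + Ap[1, 1] * dv * dv
        inside = q <= 1.0
        inside |= (
            (U >= pin_x_lo) & (U <= pin_x_hi)
            & (np.abs(V - pin_c[i1]) <= sc.pin_radius)
        )
        cov = inside.reshape(r1 - r0, s, c1 - c0, s).mean(axis=(1, 3))
        shade = simcfg.background_level + (simcfg.foreground_level - simcfg.background_level) * cov
        pixels[r0:r1, c0:c1] = np.round(shade).astype(np.uint8)
        return Frame(camera=camera, pixels=pixels, omega_at_capture=self.state.omega)

    # ------------------------------------------------------------- diffraction

    def simulate_grid_scan(
        self,
        positions: Sequence[dict],
        rng: np.random.Generator,
    ) -> List[int]:
        """Spot counts for motor targets ``[{x, y, z, omega}, ...]``.

        The expected count is ``background + peak * exp(-d^2 / (2 sigma^2))``
        with ``d`` the 3D distance from the beam (lab origin) to the crystal
        center at that motor state; the observed count is Poisson-distributed.
        """
        self._require_sample()
        sc = self.scene
        t = self.config.limits.translation_mm
        counts: List[int] = []
        for pos in positions:
            m = np.array([pos["x"], pos["y"], pos["z"]])
            if np.any(np.abs(m) > t + 1e-9):
                raise MotorLimit("grid position outside translation limits")
            lam = float(sc.background_spots)
            if sc.crystal_center is not None:
                d = np.linalg.norm(self.crystal_lab(motors=m, omega=pos["omega"]))
                lam += sc.crystal_peak_spots * math.exp(-(d**2) / (2 * sc.crystal_sigma**2))
            counts.append(int(rng.poisson(lam)))
        return counts

    def expected_spot_count(self, pos: dict) -> float:
        """Noise-free expectation at one motor target (for calibration tests)."""
        self._require_sample()
        sc = self.scene
        lam = float(sc.background_spots)
        if sc.crystal_center is not None:
            m = np.array([pos["x"], pos["y"], pos["z"]])
            d = np.linalg.norm(self.crystal_lab(motors=m, omega=pos["omega"]))
            lam += sc.crystal_peak_spots * math.exp(-(d**2) / (2 * sc.crystal_sigma**2))
        return lam
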