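"""Beamline configuration models.

Everything tunable lives here: camera geometries, motor soft limits, vision
and centering parameters, grid-scan thresholds and simulator knobs.  The
models are pydantic so a YAML config file is validated on load with useful
error coordinates.
"""
from __future__ import annotations

from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, model_validator


class CameraGeometry(BaseModel):
    """Geometry of one camera.

    ``view_axis`` is ``horizontal`` for the on-axis sample microscope (looking
    along the beam) and ``vertical`` for the wide-field top camera mounted
    above the sample, perpendicular to the omega rotation axis.  Image
    convention: origin top-left, x right, y down, 0-based pixels.
    """

    name: Literal["top", "microscope"]
    image_width: int = Field(gt=0)
    image_height: int = Field(gt=0)
    px_per_mm: float = Field(gt=0)
    beam_marker: Tuple[float, float]
    view_axis: Literal["vertical", "horizontal"]
    # Side the pin enters the frame from; the tip is the extremal foreground
    # point in this direction.
    tip_direction: Literal["+x", "-x", "+y", "-y"] = "+x"

    @model_validator(mode="after")
    def _marker_in_bounds(self) -> "CameraGeometry":
        bx, by = self.beam_marker
        if not (0 <= bx < self.image_width and 0 <= by < self.image_height):
            raise ValueError("beam_marker outside image bounds")
        return self

    @property
    def field_of_view_mm(self) -> float:
        return self.image_width / self.px_per_mm


class SoftLimits(BaseModel):
    """Motor soft limits.  Translations are symmetric about zero."""

    translation_mm: float = 5.0
    omega_deg: Tuple[float, float] = (-360.0, 360.0)
    chi_deg: Tuple[float, float] = (0.0, 40.0)
    phi_deg: Tuple[float, float] = (-360.0, 360.0)


class VisionConfig(BaseModel):
    min_component_area: int = 20          # px, reject noise specks
    roi_factor: float = 1.2               # ROI depth = factor * expected loop diameter
    expected_loop_diameter_mm: float = 0.8


class CenteringConfig(BaseModel):
    tip_tolerance_px: float = 2.0
    max_refine_rounds: int = 3
    sweep_step_deg: float = 40.0          # flat-face sweep spacing over 180 deg
    degenerate_fraction: float = 0.02     # amplitude/offset ratio below which fit is degenerate
    area_noise_sigma: float = 0.0         # optional multiplicative noise on sweep areas


class GridConfig(BaseModel):
    beam_size_mm: float = 0.05


class ThresholdConfig(BaseModel):
    """Per-mode minimum spot count for the grid-scan decision.

    The four modes mirror the operational scenarios: well diffracting
    crystals (strong), typical samples (default), weakly diffracting samples
    such as membrane proteins (weak), and always-collect which never skips.
    """

    default: int = 10
    strong: int = 40
    weak: int = 3
    always_collect: int = 0

    @model_validator(mode="after")
    def _ordering(self) -> "ThresholdConfig":
        if self.always_collect != 0:
            raise ValueError("always_collect threshold must be 0")
        if not (self.strong >= self.default >= self.weak):
            raise ValueError("threshold ordering must satisfy strong >= default >= weak")
        return self


class SimulatorConfig(BaseModel):
    mount_capture_range_mm: float = 0.5   # uniform mount-error bound per axis
    mount_failure_prob: float = 0.0
    acquisition_failure_prob: float = 0.0
    foreground_level: int = 30
    background_level: int = 230
    supersample: int = 2                  # sub-pixel sampling factor for edge coverage


class AcquisitionDefaults(BaseModel):
    """Fallback acquisition parameters for spreadsheet rows that omit them."""

    exposure_time_s: float = 0.01
    oscillation_deg: float = 0.1
    total_range_deg: float = 360.0
    transmission: float = 0.1
    resolution_a: float = 2.0


class BeamlineConfig(BaseModel):
    top_camera: CameraGeometry
    microscope_camera: CameraGeometry
    limits: SoftLimits = SoftLimits()
    vision: VisionConfig = VisionConfig()
    centering: CenteringConfig = CenteringConfig()
    grid: GridConfig = GridConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    simulator: SimulatorConfig = SimulatorConfig()
    acquisition: AcquisitionDefaults = AcquisitionDefaults()

    @model_validator(mode="after")
    def _fov_ordering(self) -> "BeamlineConfig":
        # Prelocation exists because the microscope field of view is narrow;
        # the top camera must see a wider field.
        if self.microscope_camera.field_of_view_mm >= self.top_camera.field_of_view_mm:
            raise ValueError("microscope field of view must be narrower than top camera's")
        return self

    def camera(self, name: str) -> CameraGeometry:
        if name == "top":
            return self.top_camera
        if name == "microscope":
            return self.microscope_camera
        raise KeyError(name)


def default_config() -> BeamlineConfig:
    """Desk-scale defaults: a 2.4 mm microscope field at 200 px/mm and a
    roughly 4x wider top-camera field at 50 px/mm, beam markers at the image
    centers."""
    return BeamlineConfig(
        top_camera=CameraGeometry(
            name="top", image_width=640, image_height=480,
            px_per_mm=50.0, beam_marker=(320.0, 240.0), view_axis="vertical",
        ),
        microscope_camera=CameraGeometry(
            name="microscope", image_width=480, image_height=360,
            px_per_mm=200.0, beam_marker=(240.0, 180.0), view_axis="horizontal",
        ),
    )


def load_config(path) -> BeamlineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return BeamlineConfig.model_validate(data)


def save_config(config: BeamlineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
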