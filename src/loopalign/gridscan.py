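"""Diffraction-based centering decisions.

A 2D raster scan over the loop bounding box locates the crystal in the
flat-face plane; a vertical line scan 90 degrees away resolves its position
along the former viewing axis.  Per-box spot counts are compared against a
mode-dependent threshold; when no box of a scan reaches it, the sample is
skipped.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .centering import GridPlan, _norm_omega
from .config import ThresholdConfig
from .errors import EmptyGrid
from .virtual_beamline import Frame, VirtualBeamline, rot_x

MODES = ("default", "strong", "weak", "always_collect")


@dataclass
class ThresholdPolicy:
    mode: str
    min_spots: int

    @classmethod
    def from_config(cls, mode: str, thresholds: ThresholdConfig) -> "ThresholdPolicy":
        if mode not in MODES:
            raise ValueError(f"unknown threshold mode {mode!r}")
        return cls(mode=mode, min_spots=getattr(thresholds, mode))


@dataclass
class GridScanResult:
    """Spot counts aligned with a grid plan; counts[r][c] >= 0."""

    plan: GridPlan
    counts: np.ndarray  # int, shape (nrows, ncols)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.plan.nrows, self.plan.ncols):
            raise ValueError("counts shape does not match grid geometry")
        if (self.counts < 0).any():
            raise ValueError("spot counts must be non-negative")

    @property
    def omega(self) -> float:
        return self.plan.omega

    def to_json(self) -> str:
        return json.dumps(
            {
                "omega": self.plan.omega,
                "shape": list(self.plan.shape),
                "beam_size_mm": self.plan.beam_size_mm,
                "counts": self.counts.tolist(),
            },
            sort_keys=True,
        )


@dataclass
class CenterDecision:
    outcome: str                                 # "collect" | "skip"
    position: Optional[dict] = None              # {x, y, z, omega} for collection
    best_2d_index: Optional[Tuple[int, int]] = None
    best_line_index: Optional[int] = None
    peak_2d: Optional[int] = None
    peak_line: Optional[int] = None
    result_2d: Optional[GridScanResult] = None
    result_line: Optional[GridScanResult] = None


def run_grid(bl: VirtualBeamline, plan: GridPlan, rng: np.random.Generator) -> GridScanResult:
    """Execute a grid plan on the (virtual) beamline in serpentine order and
    aggregate the per-box spot counts into grid geometry."""
    flat = bl.simulate_grid_scan(plan.ordered_targets(), rng)
    counts = np.zeros((plan.nrows, plan.ncols), dtype=int)
    for (r, c), n in zip(plan.order, flat):
        counts[r, c] = n
    return GridScanResult(plan=plan, counts=counts)


def select_best_box(res: GridScanResult, policy: ThresholdPolicy) -> Optional[Tuple[int, int]]:
    """Index of the maximum-count box, or None (skip) when every box is below
    the policy threshold.

    Ties on the count are broken by the smallest Euclidean distance of the
    box center to the grid centroid, then by row-major order.
    """
    counts = res.counts
    if counts.size == 0:
        raise EmptyGrid("grid has no boxes")
    peak = int(counts.max())
    if peak < policy.min_spots:
        return None
    rows, cols = counts.shape
    cen = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    best = None
    for r in range(rows):
        for c in range(cols):
            if counts[r, c] != peak:
                continue
            d = math.hypot(r - cen[0], c - cen[1])
            if best is None or d < best[0] - 1e-12:
                best = (d, r, c)
    return (best[1], best[2])


def line_scan_for(
    bl: VirtualBeamline,
    best_target: dict,
    bbox_height_mm: float,
    beam_size_mm: float,
    omega_2d: float,
) -> GridPlan:
    """Vertical line of motor targets at omega_2d + 90, anchored at the best
    2D box, spanning the full region-of-interest height at one beam size per
    step (same ceil rule as the 2D grid)."""
    n = max(1, math.ceil(bbox_height_mm / beam_size_mm))
    omega = _norm_omega(omega_2d + 90.0)
    Rt = rot_x(omega).T
    cam = bl.config.camera("microscope")
    bx, by = cam.beam_marker
    step_px = beam_size_mm * cam.px_per_mm
    base = np.array([best_target["x"], best_target["y"], best_target["z"]])
    targets: List[List[dict]] = []
    rects: List[List[Tuple[float, float, float, float]]] = []
    for i in range(n):
        d = (i - (n - 1) / 2.0) * beam_size_mm
        m = base + Rt @ np.array([0.0, d, 0.0])
        targets.append([{"x": float(m[0]), "y": float(m[1]), "z": float(m[2]), "omega": omega}])
        # the sample point reaching the beam at offset d sat at pixel y = by + k*d
        rects.append([(bx - step_px / 2.0, by + d * cam.px_per_mm - step_px / 2.0,
                       step_px, step_px)])
    return GridPlan(
        omega=omega, nrows=n, ncols=1, targets=targets,
        order=[(i, 0) for i in range(n)], pixel_rects=rects,
        beam_size_mm=beam_size_mm, camera="microscope",
    )


def decide(
    bl: VirtualBeamline,
    plan2d: GridPlan,
    policy: ThresholdPolicy,
    rng: np.random.Generator,
    bbox_height_mm: float,
) -> CenterDecision:
    """Full diffraction-centering decision.

    Runs the 2D raster; if some box passes the threshold, runs the vertical
    line scan through the best box and picks the best line position with the
    same policy.  The returned collect position carries the flat-face omega
    so collection happens at the 2D orientation.  A skip at either stage
    skips the sample.
    """
    res2d = run_grid(bl, plan2d, rng)
    best2 = select_best_box(res2d, policy)
    if best2 is None:
        return CenterDecision(outcome="skip", result_2d=res2d)
    r, c = best2
    line = line_scan_for(
        bl, plan2d.targets[r][c], bbox_height_mm, plan2d.beam_size_mm, plan2d.omega
    )
    resl = run_grid(bl, line, rng)
    bestl = select_best_box(resl, policy)
    if bestl is None:
        return CenterDecision(
            outcome="skip", best_2d_index=best2, peak_2d=int(res2d.counts[r, c]),
            result_2d=res2d, result_line=resl,
        )
    li = bestl[0]
    final = dict(line.targets[li][0])
    final["omega"] = plan2d.omega  # collect at the flat-face orientation
    return CenterDecision(
        outcome="collect",
        position=final,
        best_2d_index=best2,
        best_line_index=li,
        peak_2d=int(res2d.counts[r, c]),
        peak_line=int(resl.counts[li, 0]),
        result_2d=res2d,
        result_line=resl,
    )


def heat_map(frame: Frame, res: GridScanResult, alpha: float = 0.55) -> np.ndarray:
    """Overlay per-box colors (viridis, scaled over [0, max]) onto a camera
    frame; returns an RGB uint8 image."""
    base = np.stack([frame.pixels] * 3, axis=-1).astype(float)
    cmap = colormaps["viridis"]
    peak = max(1, int(res.counts.max()))
    H, W = frame.pixels.shape
    for r in range(res.plan.nrows):
        for c in range(res.plan.ncols):
            x, y, w, h = res.plan.pixel_rects[r][c]
            x0, x1 = max(0, int(round(x))), min(W, int(round(x + w)))
            y0, y1 = max(0, int(round(y))), min(H, int(round(y + h)))
            if x1 <= x0 or y1 <= y0:
                continue
            color = np.array(cmap(res.counts[r, c] / peak)[:3]) * 255.0
            base[y0:y1, x0:x1] = (1 - alpha) * base[y0:y1, x0:x1] + alpha * color
    return np.clip(np.round(base), 0, 255).astype(np.uint8)


def save_heat_map(path, frame: Frame, res: GridScanResult) -> None:
    Image.fromarray(heat_map(frame, res), mode="RGB").save(path, format="PNG")
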