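"""Silhouette image analysis: segmentation, tip finding, area, extent, bbox.

All measurements operate on binary silhouettes of a dark sample against a
light back-lit background.  The loop "region of interest" used by area,
extent and bounding-box measurements is the foreground within a configured
axial distance of the detected tip, so that the pin and gripper do not
inflate loop measurements; pass ``roi_depth_px=None`` to measure the whole
mask.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import LoopNotFound
from .virtual_beamline import Frame

PixelPoint = Tuple[int, int]  # (px, py), 0-based, x right / y down


@dataclass
class Silhouette:
    mask: np.ndarray            # bool, True = sample
    camera: str
    omega_at_capture: float


_AXIS = {"+x": (1, +1), "-x": (1, -1), "+y": (0, +1), "-y": (0, -1)}


def segment(frame: Frame, min_component_area: int = 20) -> Silhouette:
    """Binary silhouette via Otsu thresholding of the dark foreground,
    followed by morphological opening and small-component removal.

    A frame with no usable contrast yields an empty mask rather than an
    error; downstream operations raise :class:`LoopNotFound` on empty masks.
    """
    img = frame.pixels
    if int(img.max()) - int(img.min()) < 16:
        mask = np.zeros(img.shape, dtype=bool)
    else:
        thr = threshold_otsu(img)
        mask = img <= thr
        mask = ndimage.binary_opening(mask, structure=np.ones((3, 3), dtype=bool))
        labels, n = ndimage.label(mask)
        if n:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            keep = np.flatnonzero(sizes >= min_component_area) + 1
            mask = np.isin(labels, keep)
    return Silhouette(mask=mask, camera=frame.camera, omega_at_capture=frame.omega_at_capture)


def find_tip(sil: Silhouette, direction: str = "+x") -> PixelPoint:
    """Extremal foreground pixel along ``direction``; ties are broken by the
    median perpendicular coordinate of the tied set (stable and symmetric)."""
    axis, sign = _AXIS[direction]
    ys, xs = np.nonzero(sil.mask)
    if xs.size == 0:
        raise LoopNotFound("empty silhouette")
    along = xs if axis == 1 else ys
    perp = ys if axis == 1 else xs
    extreme = along.max() if sign > 0 else along.min()
    tied = np.sort(perp[along == extreme])
    med = int(tied[(tied.size - 1) // 2])
    return (int(extreme), med) if axis == 1 else (med, int(extreme))


def _roi_mask(
    sil: Silhouette,
    direction: str,
    roi_depth_px: Optional[float],
    tip: Optional[PixelPoint] = None,
) -> np.ndarray:
    if roi_depth_px is None:
        return sil.mask
    if tip is None:
        tip = find_tip(sil, direction)
    axis, sign = _AXIS[direction]
    idx = np.arange(sil.mask.shape[1] if axis == 1 else sil.mask.shape[0])
    tip_along = tip[0] if axis == 1 else tip[1]
    depth = sign * (tip_along - idx)
    keep = (depth >= 0) & (depth <= roi_depth_px)
    roi = sil.mask.copy()
    if axis == 1:
        roi[:, ~keep] = False
    else:
        roi[~keep, :] = False
    return roi


def projected_area(
    sil: Silhouette,
    direction: str = "+x",
    roi_depth_px: Optional[float] = None,
) -> int:
    """Foreground pixel count within the loop region of interest."""
    if not sil.mask.any():
        return 0
    return int(np.count_nonzero(_roi_mask(sil, direction, roi_depth_px)))


def vertical_extent(
    sil: Silhouette,
    direction: str = "+x",
    roi_depth_px: Optional[float] = None,
) -> int:
    """Pixel height (max row - min row + 1) of the region of interest."""
    roi = _roi_mask(sil, direction, roi_depth_px)
    ys, _ = np.nonzero(roi)
    if ys.size == 0:
        raise LoopNotFound("empty silhouette")
    return int(ys.max() - ys.min() + 1)


def bounding_box(
    sil: Silhouette,
    direction: str = "+x",
    roi_depth_px: Optional[float] = None,
) -> Tuple[PixelPoint, PixelPoint]:
    """Axis-aligned ((min x, min y), (max x, max y)) corners of the region of
    interest."""
    roi = _roi_mask(sil, direction, roi_depth_px)
    ys, xs = np.nonzero(roi)
    if xs.size == 0:
        raise LoopNotFound("empty silhouette")
    return (int(xs.min()), int(ys.min())), (int(xs.max()), int(ys.max()))
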