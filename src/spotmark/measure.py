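"""Flower size measurement in SI units, using the card as the scale reference.

The rectified crop spans the corner-dot-center rectangle, whose physical size
is in the configuration file, so millimetres-per-pixel comes for free — no
separate scale bar in the scene.  The flower is segmented inside a circular
region of interest around the configured flower centroid (the specimen sits in
front of a matt-black backing, so Otsu's threshold inside the region separates
it cleanly), the connected component at the centroid is kept, its holes are
filled, and area/perimeter are reported in mm^2 / mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu

from .card_spec import CardLayout
from .detect import DetectedCard, DetectionError, _luminance

__all__ = [
    "ScaleInfo",
    "FlowerMeasurement",
    "compute_scale",
    "segment_flower",
    "measure_region",
    "ROI_DIAMETER_FACTOR",
]

#: region-of-interest diameter as a multiple of the configured flower diameter;
#: keeps spot ink and corner dots out of the flower mask.
ROI_DIAMETER_FACTOR = 1.5


@dataclass(frozen=True)
class ScaleInfo:
    """Physical scale of a rectified crop."""

    mm_per_px_x: float
    mm_per_px_y: float

    @property
    def mm_per_px(self) -> float:
        """Geometric mean of the axis scales — use for areas."""
        return float(np.sqrt(self.mm_per_px_x * self.mm_per_px_y))


@dataclass
class FlowerMeasurement:
    area_mm2: float
    perimeter_mm: float
    mask: np.ndarray  # bool, same shape as the rectified crop
    flower_crop: np.ndarray  # float RGB crop of the region of interest


def compute_scale(detected: DetectedCard, layout: CardLayout) -> ScaleInfo:
    """mm-per-pixel of the rectified crop, per axis.

    The x and y scales agree within the 5% aspect tolerance (validation has
    already passed); their geometric mean is used for areas.
    """
    crop_h, crop_w = detected.rectified.shape[:2]
    return ScaleInfo(
        mm_per_px_x=layout.card_width_mm / crop_w,
        mm_per_px_y=layout.card_height_mm / crop_h,
    )


_SMOOTH_WIN = 5  # boundary smoothing window (vertices); see _boundary_length


def _boundary_length(region: np.ndarray) -> float:
    """Boundary length in pixels via a smoothed traced contour.

    The sub-pixel marching-squares contour is smoothed with a short circular
    moving average before summing segment lengths: this removes the staircase
    bias (~+5% on discs) while shaving true corners by well under 2%.
    """
    padded = np.pad(region, 1)
    total = 0.0
    for c in skmeasure.find_contours(padded.astype(float), 0.5):
        if len(c) > 1 and np.allclose(c[0], c[-1]):
            c = c[:-1]
        n = len(c)
        if n >= 3 * _SMOOTH_WIN:
            k = np.ones(_SMOOTH_WIN) / _SMOOTH_WIN
            half = _SMOOTH_WIN // 2
            sm = np.empty_like(c)
            for j in (0, 1):
                wrapped = np.r_[c[-half:, j], c[:, j], c[:half, j]]
                sm[:, j] = np.convolve(wrapped, k, mode="valid")[:n]
            c = sm
        d = np.diff(np.vstack([c, c[:1]]), axis=0)
        total += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return total


def measure_region(region: np.ndarray, mm_per_px: float) -> tuple[float, float]:
    """Area (mm^2) and perimeter (mm) of a binary region.

    Area is the exact pixel count scaled by ``mm_per_px**2``; the perimeter is
    a smoothed-contour boundary estimator with bounded bias on both smooth and
    polygonal shapes (a raw boundary-pixel count overshoots discs badly).
    """
    region = np.asarray(region, bool)
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty region")
    area = n * mm_per_px**2
    perimeter = _boundary_length(region) * mm_per_px
    return area, perimeter


def segment_flower(
    rectified: np.ndarray, layout: CardLayout, scale: ScaleInfo
) -> FlowerMeasurement:
    """Segment and measure the flower in the rectified crop.

    Requires ``layout.flower_diameter_mm > 0``.  Luminance inside the circular
    region of interest is thresholded by Otsu (flower brighter than the matt
    black backing); the component containing — or nearest to — the configured
    centroid is kept and its internal holes filled.  Raises
    ``DetectionError('FLOWER_NOT_FOUND')`` when no foreground survives.
    """
    if layout.flower_diameter_mm <= 0:
        raise ValueError("layout has no flower (flower_diameter_mm == 0)")
    crop_h, crop_w = rectified.shape[:2]
    cx = layout.flower_centroid_x_px / layout.card_width_px * crop_w
    cy = layout.flower_centroid_y_px / layout.card_height_px * crop_h
    roi_mm = ROI_DIAMETER_FACTOR * layout.flower_diameter_mm
    if layout.flower_clearance_mm > 0:
        # never sample outside the matt-black backing disc: printed card
        # (spots, labels) would otherwise leak into the flower mask
        roi_mm = min(roi_mm, layout.flower_clearance_mm - 2.0)
    r_px = roi_mm / 2 / scale.mm_per_px

    lum = _luminance(rectified[..., :3])
    yy, xx = np.mgrid[0:crop_h, 0:crop_w]
    roi = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
    if not roi.any():
        raise DetectionError("FLOWER_NOT_FOUND", "region of interest empty")
    vals = lum[roi]
    if vals.max() - vals.min() < 0.05:
        raise DetectionError(
            "FLOWER_NOT_FOUND", "no contrast inside the flower region"
        )
    thr = threshold_otsu(vals)
    fg = roi & (lum > thr)
    if not fg.any():
        raise DetectionError("FLOWER_NOT_FOUND", "no foreground above threshold")

    labels, _ = ndimage.label(fg)
    target = labels[int(round(cy)), int(round(cx))] if (
        0 <= int(round(cy)) < crop_h and 0 <= int(round(cx)) < crop_w
    ) else 0
    if target == 0:
        # nearest component to the centroid
        fg_idx = np.argwhere(labels > 0)
        d2 = (fg_idx[:, 0] - cy) ** 2 + (fg_idx[:, 1] - cx) ** 2
        target = labels[tuple(fg_idx[np.argmin(d2)])]
    mask = ndimage.binary_fill_holes(labels == target)

    area, perimeter = measure_region(mask, scale.mm_per_px)

    x0, x1 = int(max(0, cx - r_px)), int(min(crop_w, cx + r_px + 1))
    y0, y1 = int(max(0, cy - r_px)), int(min(crop_h, cy + r_px + 1))
    return FlowerMeasurement(
        area_mm2=area,
        perimeter_mm=perimeter,
        mask=mask,
        flower_crop=rectified[y0:y1, x0:x1].copy(),
    )
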