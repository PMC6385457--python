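"""Card localisation, orientation, validation and spot decoding.

The detector mirrors a strict sequential pipeline:

1. linear contrast stretch of the photo (0.5-99.5 luminance percentiles);
2. hue/saturation/value color mask for the fiducial palette; the four largest
   connected components are taken as the corner dots;
3. the dot-center discs are classified (red/green/white/black, nearest in CIE
   Lab) and the two diagonal directions (red->black, green->white) give the
   in-plane rotation that puts the red-centered dot top-left;
4. the image is rigidly rotated (no perspective correction) and cropped to the
   corner-dot centers;
5. geometric validation: opposing diagonals within 5% of each other, cropped
   aspect ratio within 5% of the configured card, and the top-left center disc
   red;
6. each spot's central window (25% of the spot width/height) is averaged; mean
   gray below the mark threshold means inked.

Every failure carries a machine-readable error code and aborts only the current
image: decoding soft-fails per category (MISSING / AMBIGUOUS) instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure as skmeasure
from skimage.color import rgb2hsv, rgb2lab
from skimage.transform import SimilarityTransform, warp

from .card_generate import CENTER_RGB
from .card_spec import CardLayout, SpotGeometry

__all__ = [
    "DetectedCard",
    "CardReading",
    "DetectionError",
    "MISSING",
    "AMBIGUOUS",
    "adjust_contrast",
    "find_corner_dots",
    "identify_orientation",
    "rectify_and_validate",
    "read_spot",
    "decode",
    "analyse_image",
    "DEFAULT_MARK_THRESHOLD",
]

DEFAULT_MARK_THRESHOLD = 128.0
DIAG_RATIO_MIN = 0.95
ASPECT_TOL = 0.05
MIN_DOT_DIAMETER_PX = 60.0

MISSING = "MISSING"
AMBIGUOUS = "AMBIGUOUS"

# HSV box masks for the fiducial palettes, wide enough to survive +-30%
# illumination scaling and JPEG compression of the generator's colors.
_HSV_MASKS = {
    "blue": {"hue": (0.52, 0.78), "sat": 0.40, "val": 0.18},
    "pink": {"hue": (0.82, 0.99), "sat": 0.25, "val": 0.35},
}

_LAB_REFS = {
    name: rgb2lab(np.array(rgb, float).reshape(1, 1, 3) / 255.0)[0, 0]
    for name, rgb in CENTER_RGB.items()
}

_CORNER_OF_COLOR = {"red": "TL", "green": "TR", "white": "BL", "black": "BR"}


class DetectionError(RuntimeError):
    """A per-image failure with a machine-readable ``code``."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass
class DotRegion:
    centroid: tuple[float, float]  # (x, y)
    area: float
    equivalent_diameter: float
    bbox_diameter: float
    center_color: str | None = None


@dataclass
class DetectedCard:
    """Localisation result: labeled corners, rectified crop and scale."""

    corner_centers: dict[str, tuple[float, float]]  # TL/TR/BL/BR in photo coords
    rotation_deg: float
    rectified: np.ndarray  # float RGB in [0,1], cropped to dot centers
    mm_per_px: float
    diag_ratio: float
    aspect_error: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class CardReading:
    """Decoded value per category plus the raw per-spot readings."""

    values: dict[str, str]  # category name -> label / MISSING / AMBIGUOUS
    spot_means: list[float]
    status: str = "ok"
    error_code: str | None = None
    error_message: str | None = None


def _luminance(rgb: np.ndarray) -> np.ndarray:
    return rgb @ np.array([0.2126, 0.7152, 0.0722])


def adjust_contrast(image: np.ndarray) -> np.ndarray:
    """Linear stretch mapping the 0.5/99.5 luminance percentiles to 0/1.

    Accepts uint8 or float RGB; returns float RGB in [0,1].  The same linear
    map is applied to all channels so hue is preserved.
    """
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    else:
        img = img.astype(np.float64)
    lum = _luminance(img)
    lo, hi = np.percentile(lum, [0.5, 99.5])
    if hi - lo < 1e-6:
        return np.clip(img, 0.0, 1.0)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def find_corner_dots(image: np.ndarray, palette: str = "blue") -> list[DotRegion]:
    """Locate the four fiducial dots as the four largest palette-colored blobs.

    ``image`` is the contrast-adjusted float RGB photo.  Smaller same-colored
    noise is ignored by construction (largest-four rule); fewer than four
    blobs raises ``CORNERS_NOT_FOUND``.
    """
    spec = _HSV_MASKS[palette]
    hsv = rgb2hsv(image)
    mask = (
        (hsv[..., 0] >= spec["hue"][0])
        & (hsv[..., 0] <= spec["hue"][1])
        & (hsv[..., 1] >= spec["sat"])
        & (hsv[..., 2] >= spec["val"])
    )
    labels = skmeasure.label(mask, connectivity=2)
    props = skmeasure.regionprops(labels)
    props = [p for p in props if p.area >= 9]
    props.sort(key=lambda p: p.area, reverse=True)
    if len(props) < 4:
        raise DetectionError(
            "CORNERS_NOT_FOUND",
            f"found {len(props)} {palette} regions; need 4 corner dots",
        )
    regions = []
    for p in props[:4]:
        cy, cx = p.centroid
        minr, minc, maxr, maxc = p.bbox
        regions.append(
            DotRegion(
                centroid=(float(cx), float(cy)),
                area=float(p.area),
                equivalent_diameter=float(p.equivalent_diameter_area),
                bbox_diameter=float(max(maxr - minr, maxc - minc)),
            )
        )
    return regions


def _classify_center(image: np.ndarray, region: DotRegion) -> str:
    """Nearest Lab reference color of the dot's central disc."""
    cx, cy = region.centroid
    r = max(2.0, region.bbox_diameter / 6 * 0.7)
    h, w = image.shape[:2]
    y0, y1 = int(max(0, cy - r)), int(min(h, cy + r + 1))
    x0, x1 = int(max(0, cx - r)), int(min(w, cx + r + 1))
    patch = image[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    if not inside.any():
        raise DetectionError("CENTERS_UNRESOLVED", "dot center sample empty")
    mean_rgb = patch[inside].mean(axis=0)
    lab = rgb2lab(mean_rgb.reshape(1, 1, 3))[0, 0]
    dists = {name: float(np.linalg.norm(lab - ref)) for name, ref in _LAB_REFS.items()}
    return min(dists, key=dists.get)


def identify_orientation(
    image: np.ndarray, regions: list[DotRegion]
) -> tuple[dict[str, DotRegion], float]:
    """Label the four dots by center color and compute the in-plane rotation.

    The red->black and green->white diagonal directions are averaged; on an
    upright card their vector sum points straight down, so the angle that
    brings the observed sum to +y is the rotation to apply.  Returns
    ``({'TL': region, ...}, rotation_deg)`` (counter-clockwise positive in
    image coordinates, i.e. y down).
    """
    by_corner: dict[str, DotRegion] = {}
    for reg in regions:
        color = _classify_center(image, reg)
        reg.center_color = color
        corner = _CORNER_OF_COLOR[color]
        if corner in by_corner:
            raise DetectionError(
                "CENTERS_UNRESOLVED", f"two corner dots classified {color!r}"
            )
        by_corner[corner] = reg
    if set(by_corner) != {"TL", "TR", "BL", "BR"}:
        raise DetectionError(
            "CENTERS_UNRESOLVED",
            f"center colors resolve to {sorted(by_corner)}; need all four",
        )

    def unit(a: DotRegion, b: DotRegion) -> np.ndarray:
        v = np.subtract(b.centroid, a.centroid)
        n = np.linalg.norm(v)
        if n < 1e-9:
            raise DetectionError("CENTERS_UNRESOLVED", "coincident corner dots")
        return v / n

    s = unit(by_corner["TL"], by_corner["BR"]) + unit(by_corner["TR"], by_corner["BL"])
    if np.linalg.norm(s) < 1e-9:
        raise DetectionError("CENTERS_UNRESOLVED", "degenerate diagonal geometry")
    # rotation that maps the summed diagonal direction onto +y (downwards)
    rotation = 90.0 - np.degrees(np.arctan2(s[1], s[0]))
    rotation = (rotation + 180.0) % 360.0 - 180.0
    return by_corner, float(rotation)


def _rotate_image_and_points(
    image: np.ndarray, points: np.ndarray, angle_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid CCW rotation about the image center, canvas expanded to fit."""
    h, w = image.shape[:2]
    theta = np.radians(angle_deg)
    center = np.array([(w - 1) / 2, (h - 1) / 2])
    tform = (
        SimilarityTransform(translation=-center)
        + SimilarityTransform(rotation=theta)
    )
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
    moved = tform(corners)
    shift = moved.min(axis=0)
    tform = tform + SimilarityTransform(translation=-shift)
    out_shape = np.ceil(moved.max(axis=0) - shift).astype(int)[::-1] + 1
    rotated = warp(
        image,
        tform.inverse,
        output_shape=(out_shape[0], out_shape[1]),
        order=1,
        cval=1.0,
    )
    return rotated, tform(points)


def rectify_and_validate(
    image: np.ndarray, corners: dict[str, DotRegion], layout: CardLayout
) -> DetectedCard:
    """Rotate upright, crop to the dot centers, and run the validation checks.

    Checks, in order: (1) opposing diagonal lengths within 5% of each other;
    (2) cropped aspect ratio within 5% of the configured card's; (3) the
    central portion of the top-left dot is red.  Any failure raises
    :class:`DetectionError` with the corresponding code.
    """
    pts = np.array([corners[k].centroid for k in ("TL", "TR", "BL", "BR")], float)

    d1 = np.linalg.norm(pts[0] - pts[3])  # TL-BR (red-black)
    d2 = np.linalg.norm(pts[1] - pts[2])  # TR-BL (green-white)
    diag_ratio = min(d1, d2) / max(d1, d2)
    if diag_ratio < DIAG_RATIO_MIN:
        raise DetectionError(
            "DIAGONAL_MISMATCH",
            f"diagonal ratio {diag_ratio:.4f} below {DIAG_RATIO_MIN} "
            "(card tilted too far)",
        )

    # recompute the rotation from the labeled corners so this operation is
    # usable standalone (identify_orientation derives the same quantity)
    s = pts[3] - pts[0]
    s = s / np.linalg.norm(s)
    t = pts[2] - pts[1]
    t = t / np.linalg.norm(t)
    v = s + t
    rotation = 90.0 - np.degrees(np.arctan2(v[1], v[0]))
    rotation = (rotation + 180.0) % 360.0 - 180.0

    rotated, new_pts = _rotate_image_and_points(image, pts, rotation)
    # crop edges: average the two dot centers on each side.  Under pure
    # rotation this equals their common coordinate; under residual keystone it
    # cancels the near/far-edge size difference to first order.
    tl, tr, bl, br = new_pts
    x0 = (tl[0] + bl[0]) / 2
    x1 = (tr[0] + br[0]) / 2
    y0 = (tl[1] + tr[1]) / 2
    y1 = (bl[1] + br[1]) / 2
    xi0, yi0 = int(round(x0)), int(round(y0))
    xi1, yi1 = int(round(x1)), int(round(y1))
    h, w = rotated.shape[:2]
    xi0, yi0 = max(0, xi0), max(0, yi0)
    xi1, yi1 = min(w - 1, xi1), min(h - 1, yi1)
    if xi1 - xi0 < 4 or yi1 - yi0 < 4:
        raise DetectionError("ASPECT_MISMATCH", "degenerate crop")
    rectified = rotated[yi0 : yi1 + 1, xi0 : xi1 + 1]

    crop_h, crop_w = rectified.shape[:2]
    observed = crop_w / crop_h
    aspect_error = abs(observed - layout.aspect_ratio) / layout.aspect_ratio
    if aspect_error > ASPECT_TOL:
        raise DetectionError(
            "ASPECT_MISMATCH",
            f"cropped aspect ratio {observed:.4f} differs from configured "
            f"{layout.aspect_ratio:.4f} by {aspect_error:.1%} (> {ASPECT_TOL:.0%})",
        )

    # orientation confirmation: the central portion of the top-left dot must
    # be red.  Sample around the tracked TL dot center (residual shear from a
    # tilt about a diagonal can move it a little inside the crop corner).
    rc = max(2.0, layout.dot_diameter_mm / 6 * (crop_w / layout.card_width_mm) * 0.5)
    rh, rw = rotated.shape[:2]
    px0, px1 = int(max(0, tl[0] - rc)), int(min(rw, tl[0] + rc + 1))
    py0, py1 = int(max(0, tl[1] - rc)), int(min(rh, tl[1] + rc + 1))
    if px1 <= px0 or py1 <= py0:
        raise DetectionError(
            "ORIENTATION_CHECK_FAILED", "top-left dot center outside the image"
        )
    patch = rotated[py0:py1, px0:px1]
    lab = rgb2lab(patch.mean(axis=(0, 1)).reshape(1, 1, 3))[0, 0]
    dists = {nm: float(np.linalg.norm(lab - ref)) for nm, ref in _LAB_REFS.items()}
    if min(dists, key=dists.get) != "red":
        raise DetectionError(
            "ORIENTATION_CHECK_FAILED",
            "top-left dot center is not red after rectification",
        )

    warnings_ = []
    for key, reg in corners.items():
        if reg.bbox_diameter < MIN_DOT_DIAMETER_PX:
            warnings_.append(
                f"DOT_TOO_SMALL: {key} dot ~{reg.bbox_diameter:.0f} px "
                f"(< {MIN_DOT_DIAMETER_PX:.0f} px recommended)"
            )

    return DetectedCard(
        corner_centers={k: corners[k].centroid for k in ("TL", "TR", "BL", "BR")},
        rotation_deg=rotation,
        rectified=rectified,
        mm_per_px=layout.card_width_mm / crop_w,
        diag_ratio=float(diag_ratio),
        aspect_error=float(aspect_error),
        warnings=warnings_,
    )


def read_spot(
    rectified: np.ndarray, spot: SpotGeometry, layout: CardLayout
) -> float:
    """Mean gray (0-255) of the spot's central window (25% of its size).

    Template coordinates are mapped onto the crop by independent x and y
    linear scales, which compensates the uniform foreshortening of a mildly
    tilted card.
    """
    crop_h, crop_w = rectified.shape[:2]
    sx = crop_w / layout.card_width_px
    sy = crop_h / layout.card_height_px
    cx, cy = spot.x * sx, spot.y * sy
    hw = max(1.0, 0.25 * spot.width * sx / 2)
    hh = max(1.0, 0.25 * spot.height * sy / 2)
    x0, x1 = int(round(cx - hw)), int(round(cx + hw))
    y0, y1 = int(round(cy - hh)), int(round(cy + hh))
    if x0 < 0 or y0 < 0 or x1 > crop_w or y1 > crop_h:
        raise DetectionError(
            "SPOT_OUT_OF_BOUNDS",
            f"spot {spot.value_label!r} window falls outside the crop",
        )
    window = rectified[y0:y1, x0:x1]
    return float(_luminance(window).mean() * 255.0)


def decode(
    spot_means: list[float],
    layout: CardLayout,
    mark_threshold: float = DEFAULT_MARK_THRESHOLD,
) -> CardReading:
    """Turn per-spot mean grays into per-category values.

    A mean below ``mark_threshold`` marks the spot.  Per explicit category (or
    per digit row): zero marks -> MISSING, more than one -> AMBIGUOUS; neither
    fails the image.
    """
    marked = [m < mark_threshold for m in spot_means]
    values: dict[str, str] = {}
    for ci, cat in enumerate(layout.categories):
        if cat.mode == "explicit":
            hits = [
                s.value_label
                for i, s in enumerate(layout.spots)
                if s.category_index == ci and marked[i]
            ]
            if len(hits) == 1:
                values[cat.name] = hits[0]
            else:
                values[cat.name] = MISSING if not hits else AMBIGUOUS
        else:
            digits: dict[int, int] = {}
            bad = None
            for row in range(cat.n_rows):
                hits = [
                    int(s.value_label)
                    for i, s in enumerate(layout.spots)
                    if s.category_index == ci and s.row_index == row and marked[i]
                ]
                if len(hits) == 1:
                    digits[row] = hits[0]
                else:
                    bad = MISSING if not hits else AMBIGUOUS
                    break
            if bad:
                values[cat.name] = bad
            else:
                values[cat.name] = str(
                    int("".join(str(digits[r]) for r in range(cat.n_rows)))
                )
    return CardReading(values=values, spot_means=list(spot_means))


def analyse_image(
    image: np.ndarray,
    layout: CardLayout,
    mark_threshold: float = DEFAULT_MARK_THRESHOLD,
) -> tuple[DetectedCard, CardReading]:
    """Full per-image pipeline: locate, orient, validate, read, decode.

    Raises :class:`DetectionError` on any hard validation failure; decoding
    problems surface as MISSING/AMBIGUOUS values in the returned reading.
    """
    adjusted = adjust_contrast(image)
    regions = find_corner_dots(adjusted, layout.dot_palette)
    corners, _ = identify_orientation(adjusted, regions)
    detected = rectify_and_validate(adjusted, corners, layout)
    means = [read_spot(detected.rectified, s, layout) for s in layout.spots]
    reading = decode(means, layout, mark_threshold)
    return detected, reading
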