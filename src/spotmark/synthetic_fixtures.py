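"""Synthetic ground-truth photographs of marked cards.

Every other module is testable without real field data: this module renders a
card (via :mod:`spotmark.card_generate`), inks a chosen mark set, optionally
paints a flower disc on the matt-black backing, and composites the card into a
"photograph" under controlled in-plane rotation, out-of-plane tilt (pinhole
camera at a configurable distance, default 10 card widths; ``None`` gives an
orthographic projection), scale, noise, illumination gradient, distractors and
injected EXIF tags.  The full ground truth (marks, expected decoded values,
projected corner positions, expected diagonal ratio, flower geometry) rides
along as a JSON sidecar and is the oracle for every test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw
from PIL.TiffImagePlugin import IFDRational
from skimage.transform import ProjectiveTransform, warp

from . import card_generate
from .card_spec import CardLayout
from .card_generate import (
    PRINT_MARGIN_MM,
    marks_to_spot_indices,
    render_card,
)
from .detect import MISSING

__all__ = [
    "FixtureSpec",
    "ExifFixture",
    "render_fixture",
    "save_fixture",
    "sweep",
    "fig1_categories",
    "expected_values",
]

FLOWER_RGB = (245, 235, 205)  # cream petals, bright against the black backing
BACKING_RGB = (25, 25, 25)  # matt black card behind the flower
LEAF_RGB = (40, 110, 35)
CANVAS_PAD_PX = 24


@dataclass
class ExifFixture:
    datetime: str = "2023:06:01 10:30:00"
    latitude: float | None = 52.205
    longitude: float | None = 0.125
    altitude: float | None = 12.0


@dataclass
class FixtureSpec:
    """Everything needed to render one ground-truth photograph."""

    layout: CardLayout
    marks: dict[int, object] = field(default_factory=dict)
    rotation_deg: float = 0.0
    tilt_deg: float = 0.0
    tilt_axis: str = "x"  # "x" | "y" | "diag" | "antidiag"
    px_per_mm: float = 7.0
    camera_distance_factor: float | None = 10.0  # card widths; None = orthographic
    background: str = "plain"  # "plain" | "textured"
    distractor_px: int = 0  # blue distractor disc diameter (0 = none)
    occlude_corner: str | None = None  # "TL" | "TR" | "BL" | "BR"
    reflection_spot: int | None = None  # spot index blown out by a reflection
    flower_radius_mm: float = 0.0
    flower_aspect: float = 1.0  # minor/major axis ratio for an ellipse
    noise_sigma: float = 0.0  # additive Gaussian, 0-255 scale
    illumination_gradient: float = 0.0  # +-fractional ramp across the frame
    exif: ExifFixture | None = None
    seed: int = 0


def fig1_categories() -> list:
    """The worked three-category example: Variety A-D, Flower 1-3, Plant 0-99."""
    from .card_spec import parse_category_input

    return [
        parse_category_input("Variety", "A, B, C, D"),
        parse_category_input("Flower", "1, 2, 3"),
        parse_category_input("Plant", "0-99"),
    ]


def expected_values(layout: CardLayout, marks: dict[int, object]) -> dict[str, str]:
    """Ground-truth decoded values (unmarked categories are MISSING)."""
    out = {}
    for ci, cat in enumerate(layout.categories):
        if ci in marks:
            v = marks[ci]
            out[cat.name] = str(int(v)) if cat.mode == "integer_range" else str(v)
        else:
            out[cat.name] = MISSING
    return out


def _tilt_axis_vector(spec: FixtureSpec) -> np.ndarray:
    w, h = spec.layout.card_width_mm, spec.layout.card_height_mm
    if spec.tilt_axis == "x":
        v = np.array([1.0, 0.0])
    elif spec.tilt_axis == "y":
        v = np.array([0.0, 1.0])
    elif spec.tilt_axis == "diag":  # along the TL->BR diagonal
        v = np.array([w, h])
    elif spec.tilt_axis == "antidiag":
        v = np.array([w, -h])
    else:
        raise ValueError(f"unknown tilt axis {spec.tilt_axis!r}")
    return v / np.linalg.norm(v)


def _projector(spec: FixtureSpec):
    """Map template-image pixel coordinates to centered photo-mm coordinates."""
    layout = spec.layout
    ppm_t = layout.px_per_mm
    margin = PRINT_MARGIN_MM * ppm_t
    w_mm, h_mm = layout.card_width_mm, layout.card_height_mm
    u2 = _tilt_axis_vector(spec)
    axis = np.array([u2[0], u2[1], 0.0])
    t = math.radians(spec.tilt_deg)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    R = np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)
    d = (
        None
        if spec.camera_distance_factor is None
        else spec.camera_distance_factor * w_mm
    )
    th = math.radians(spec.rotation_deg)
    Rot2 = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])

    def project(pts_template_px: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_template_px, float))
        X = (pts[:, 0] - margin) / ppm_t - w_mm / 2
        Y = (pts[:, 1] - margin) / ppm_t - h_mm / 2
        P = np.stack([X, Y, np.zeros_like(X)], axis=1) @ R.T
        if d is None:
            proj = P[:, :2]
        else:
            # pinhole at z=+d: points tilted toward the camera appear larger
            proj = P[:, :2] * (d / (d - P[:, 2]))[:, None]
        return (proj @ Rot2.T) * spec.px_per_mm

    return project


def render_fixture(spec: FixtureSpec) -> tuple[np.ndarray, dict]:
    """Render the photograph and return ``(uint8 RGB array, ground truth)``."""
    layout = spec.layout
    rng = np.random.default_rng(spec.seed)
    marked = marks_to_spot_indices(layout, spec.marks)
    card = render_card(layout, marked_spots=marked).copy()

    # paint the matt-black backing disc and the flower through the slit
    if layout.flower_clearance_mm > 0:
        img = Image.fromarray(card)
        drw = ImageDraw.Draw(img)
        ppm_t = layout.px_per_mm
        m = PRINT_MARGIN_MM * ppm_t
        cx = layout.flower_centroid_x_px + m
        cy = layout.flower_centroid_y_px + m
        rb = layout.flower_clearance_mm / 2 * ppm_t
        drw.ellipse([cx - rb, cy - rb, cx + rb, cy + rb], fill=BACKING_RGB)
        if spec.flower_radius_mm > 0:
            ra = spec.flower_radius_mm * ppm_t
            rbm = ra * spec.flower_aspect
            drw.ellipse([cx - ra, cy - rbm, cx + ra, cy + rbm], fill=FLOWER_RGB)
        card = np.asarray(img).copy()

    if spec.reflection_spot is not None:
        img = Image.fromarray(card)
        drw = ImageDraw.Draw(img)
        s = layout.spots[spec.reflection_spot]
        m = PRINT_MARGIN_MM * layout.px_per_mm
        r = s.width * 0.65
        drw.ellipse(
            [s.x + m - r, s.y + m - r, s.x + m + r, s.y + m + r],
            fill=(255, 255, 255),
        )
        card = np.asarray(img).copy()

    project = _projector(spec)
    th, tw = card.shape[:2]
    src = np.array([[0, 0], [tw - 1, 0], [0, th - 1], [tw - 1, th - 1]], float)
    proj = project(src)
    lo = proj.min(axis=0)
    hi = proj.max(axis=0)
    pad = CANVAS_PAD_PX
    extra_w = 3 * spec.distractor_px if spec.distractor_px else 0
    offset = pad - lo
    canvas_w = int(math.ceil(hi[0] - lo[0])) + 2 * pad + extra_w
    canvas_h = int(math.ceil(hi[1] - lo[1])) + 2 * pad

    def to_canvas(pts_template_px: np.ndarray) -> np.ndarray:
        return project(pts_template_px) + offset

    dst = proj + offset
    tform = ProjectiveTransform.from_estimate(src, dst)
    if not tform:
        raise ValueError("could not estimate fixture homography")

    # background
    if spec.background == "textured":
        from scipy.ndimage import gaussian_filter

        base = rng.normal(0.0, 1.0, (canvas_h, canvas_w))
        base = gaussian_filter(base, 6.0)
        base = (base - base.min()) / max(1e-9, float(base.max() - base.min()))
        bg = np.stack(
            [0.25 + 0.2 * base, 0.35 + 0.25 * base, 0.2 + 0.15 * base], axis=-1
        )
    else:
        bg = np.full((canvas_h, canvas_w, 3), 0.0)
        bg[...] = np.array([110, 130, 95]) / 255.0

    warped = warp(
        card.astype(float) / 255.0,
        tform.inverse,
        output_shape=(canvas_h, canvas_w),
        order=1,
        cval=0.0,
    )
    mask = warp(
        np.ones((th, tw)),
        tform.inverse,
        output_shape=(canvas_h, canvas_w),
        order=1,
        cval=0.0,
    )
    photo = bg * (1 - mask[..., None]) + warped * mask[..., None]

    # corner-dot centers in canvas coordinates (ground truth + occlusion)
    m = PRINT_MARGIN_MM * layout.px_per_mm
    dot_template = {
        "TL": (m, m),
        "TR": (m + layout.card_width_px, m),
        "BL": (m, m + layout.card_height_px),
        "BR": (m + layout.card_width_px, m + layout.card_height_px),
    }
    dot_canvas = {k: to_canvas(np.array([v]))[0] for k, v in dot_template.items()}

    img = Image.fromarray((np.clip(photo, 0, 1) * 255).astype(np.uint8))
    drw = ImageDraw.Draw(img)
    if spec.occlude_corner:
        cx, cy = dot_canvas[spec.occlude_corner]
        r = layout.dot_diameter_mm * spec.px_per_mm * 0.9
        drw.ellipse([cx - r, cy - r * 0.7, cx + r, cy + r * 0.7], fill=LEAF_RGB)
    if spec.distractor_px:
        r = spec.distractor_px / 2
        cx = canvas_w - pad - r
        cy = canvas_h / 2
        drw.ellipse(
            [cx - r, cy - r, cx + r, cy + r],
            fill=card_generate.PALETTE_RGB[layout.dot_palette],
        )
    photo = np.asarray(img).astype(float) / 255.0

    if spec.illumination_gradient:
        g = spec.illumination_gradient
        ramp = np.linspace(1 - g, 1 + g, canvas_w)
        photo = photo * ramp[None, :, None]
    if spec.noise_sigma:
        photo = photo + rng.normal(0.0, spec.noise_sigma / 255.0, photo.shape)
    arr = (np.clip(photo, 0, 1) * 255).astype(np.uint8)

    d1 = np.linalg.norm(dot_canvas["TL"] - dot_canvas["BR"])
    d2 = np.linalg.norm(dot_canvas["TR"] - dot_canvas["BL"])
    truth = {
        "marks": {str(k): v for k, v in spec.marks.items()},
        "expected_values": expected_values(layout, spec.marks),
        "rotation_deg": spec.rotation_deg,
        "tilt_deg": spec.tilt_deg,
        "tilt_axis": spec.tilt_axis,
        "px_per_mm": spec.px_per_mm,
        "dot_centers": {k: list(map(float, v)) for k, v in dot_canvas.items()},
        "diag_ratio": float(min(d1, d2) / max(d1, d2)),
        "flower_radius_mm": spec.flower_radius_mm,
        "flower_area_mm2": (
            math.pi * spec.flower_radius_mm**2 * spec.flower_aspect
            if spec.flower_radius_mm
            else None
        ),
        "flower_perimeter_mm": (
            2 * math.pi * spec.flower_radius_mm
            if spec.flower_radius_mm and spec.flower_aspect == 1.0
            else None
        ),
        "occlude_corner": spec.occlude_corner,
        "distractor_px": spec.distractor_px,
        "reflection_spot": spec.reflection_spot,
        "exif": asdict(spec.exif) if spec.exif else None,
        "seed": spec.seed,
    }
    return arr, truth


def _exif_payload(ex: ExifFixture) -> Image.Exif:
    from .metadata_io import decimal_to_dms

    exif = Image.Exif()
    exif[0x0132] = ex.datetime
    exif[0x8769] = {0x9003: ex.datetime}
    gps: dict[int, object] = {}

    def rat(x: float) -> IFDRational:
        return IFDRational(int(round(x * 10000)), 10000)

    if ex.latitude is not None:
        (d, mnt, s), pos = decimal_to_dms(ex.latitude)
        gps[1] = "N" if pos else "S"
        gps[2] = (IFDRational(d, 1), IFDRational(mnt, 1), rat(s))
    if ex.longitude is not None:
        (d, mnt, s), pos = decimal_to_dms(ex.longitude)
        gps[3] = "E" if pos else "W"
        gps[4] = (IFDRational(d, 1), IFDRational(mnt, 1), rat(s))
    if ex.altitude is not None:
        gps[5] = b"\x01" if ex.altitude < 0 else b"\x00"
        gps[6] = rat(abs(ex.altitude))
    if gps:
        exif[0x8825] = gps
    return exif


def save_fixture(spec: FixtureSpec, path: str | Path) -> tuple[Path, dict]:
    """Render, save the image (EXIF injected for JPEG) and its truth sidecar."""
    path = Path(path)
    arr, truth = render_fixture(spec)
    img = Image.fromarray(arr)
    if spec.exif is not None and path.suffix.lower() in (".jpg", ".jpeg"):
        img.save(path, quality=95, exif=_exif_payload(spec.exif))
    elif path.suffix.lower() in (".jpg", ".jpeg"):
        img.save(path, quality=95)
    else:
        img.save(path)
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    sidecar.write_text(json.dumps(truth, indent=1), encoding="utf-8")
    return path, truth


def sweep(
    axis: str, values, base: FixtureSpec, mark_threshold: float | None = None
) -> list[dict]:
    """Render one fixture per parameter value and tabulate detection outcomes.

    Supported axes: ``tilt_deg``, ``rotation_deg``, ``px_per_mm``,
    ``noise_sigma``, ``dot_diameter_px`` (which drives the render scale).
    Each row reports the validation outcome and whether every ground-truth
    value was decoded exactly.
    """
    from dataclasses import replace

    from .detect import DEFAULT_MARK_THRESHOLD, DetectionError, analyse_image

    thr = DEFAULT_MARK_THRESHOLD if mark_threshold is None else mark_threshold
    rows = []
    for v in values:
        if axis == "dot_diameter_px":
            spec = replace(base, px_per_mm=float(v) / base.layout.dot_diameter_mm)
        elif axis in ("tilt_deg", "rotation_deg", "px_per_mm", "noise_sigma"):
            spec = replace(base, **{axis: v})
        else:
            raise ValueError(f"unsupported sweep axis {axis!r}")
        arr, truth = render_fixture(spec)
        row = {"value": v, "error": "", "decode_exact": False}
        try:
            detected, reading = analyse_image(arr, spec.layout, thr)
            row["diag_ratio"] = detected.diag_ratio
            row["aspect_error"] = detected.aspect_error
            row["decode_exact"] = reading.values == truth["expected_values"]
            row["values"] = reading.values
        except DetectionError as exc:
            row["error"] = exc.code
        rows.append(row)
    return rows
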