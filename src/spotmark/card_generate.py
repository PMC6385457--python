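"""Layout and rendering of printable annotation cards.

``layout_card`` turns a list of categories into a deterministic
:class:`~spotmark.card_spec.CardLayout`; ``render_card`` rasterises it (spot
outlines with printed value labels, category captions, the stem-slit indicator
and the four colored fiducial corner dots).  All layout constants are module
constants in millimetres; the template raster is produced at ``DEFAULT_DPI``.

Integer-range categories encode a number by marking one digit spot per row
(most-significant row first, leading zeros marked explicitly), e.g. 532 marks
the 5 in the hundreds row, the 3 in the tens row and the 2 in the units row.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .card_spec import CardLayout, CategorySpec, ConfigError, SpotGeometry

__all__ = [
    "layout_card",
    "render_card",
    "save_card",
    "encode_integer",
    "decode_digits",
    "marks_to_spot_indices",
    "DEFAULT_DPI",
    "PALETTE_RGB",
    "CENTER_RGB",
]

DEFAULT_DPI = 300

# layout constants (mm)
SPOT_DIAMETER_MM = 6.0
SPOT_PITCH_MM = 8.0
DOT_DIAMETER_MM = 10.0
EDGE_INSET_MM = 9.0  # dot-center rectangle edge -> spot area
LABEL_HEIGHT_MM = 5.0
GROUP_GAP_MM = 3.0
CLEARANCE_MARGIN_MM = 6.0  # added to the flower diameter for the spot-free circle
PRINT_MARGIN_MM = 7.0  # printed paper beyond the dot centers

#: fiducial dot body colors; blue is the default because it is rare in plants,
#: pink is for photographing blue samples.
PALETTE_RGB = {"blue": (30, 60, 220), "pink": (236, 60, 160)}

#: orientation-disc colors at the dot centers.
CENTER_RGB = {
    "red": (220, 30, 30),
    "green": (30, 160, 40),
    "white": (255, 255, 255),
    "black": (10, 10, 10),
}

INK_GRAY = 20  # dry-wipe marker emulation (used by the synthetic fixtures)


def encode_integer(n: int, spec: CategorySpec) -> frozenset[tuple[int, int]]:
    """Digit marks for ``n`` on an integer-range category.

    Returns ``{(row_index, digit), ...}`` with exactly one digit per row and
    leading zeros marked explicitly, so every row always carries one mark.
    """
    if spec.mode != "integer_range":
        raise ConfigError(f"category {spec.name!r} is not an integer range")
    if not 0 <= n <= spec.range_max:
        raise ConfigError(f"{n} outside range 0-{spec.range_max}")
    digits = str(n).zfill(spec.n_rows)
    return frozenset((row, int(d)) for row, d in enumerate(digits))


def decode_digits(marks: dict[int, int], spec: CategorySpec) -> int:
    """Inverse of :func:`encode_integer`: row->digit mapping to integer."""
    if sorted(marks) != list(range(spec.n_rows)):
        raise ConfigError("need exactly one digit per row")
    return int("".join(str(marks[r]) for r in range(spec.n_rows)))


def marks_to_spot_indices(layout: CardLayout, marks: dict[int, object]) -> set[int]:
    """Spot indices to ink for a chosen value per category.

    ``marks`` maps category index to the chosen value: a label for explicit
    categories, an int for integer ranges.  Categories absent from ``marks``
    are left blank.
    """
    inked: set[int] = set()
    for ci, value in marks.items():
        cat = layout.categories[ci]
        if cat.mode == "explicit":
            wanted = {(0, str(value))}
        else:
            wanted = {(row, str(d)) for row, d in encode_integer(int(value), cat)}
        for i, s in enumerate(layout.spots):
            if s.category_index == ci and (s.row_index, s.value_label) in wanted:
                inked.add(i)
    return inked


def layout_card(
    categories: list[CategorySpec],
    flower_diameter_mm: float = 0.0,
    palette: str = "blue",
    dpi: int = DEFAULT_DPI,
    min_width_mm: float | None = None,
    min_height_mm: float | None = None,
) -> CardLayout:
    """Compute a deterministic card layout.

    With a flower diameter, a spot-free circular clearance (diameter + margin)
    sits in the upper center — the slit for the stem is cut down to it — and
    the category groups stack below.  Without one, groups simply stack from the
    top.  ``min_width_mm``/``min_height_mm`` pad the card up to a requested
    physical size (spots keep their positions relative to the top-left).
    """
    if not categories:
        raise ConfigError("need at least one category")
    if flower_diameter_mm < 0:
        raise ConfigError("flower_diameter_mm must be >= 0")
    if flower_diameter_mm and not 20 <= flower_diameter_mm <= 100:
        warnings.warn(
            f"flower diameter {flower_diameter_mm} mm is outside the 20-100 mm "
            "presets",
            stacklevel=2,
        )
    if len(categories) > 9:
        warnings.warn(
            f"{len(categories)} categories; cards beyond ~9 become impractically "
            "large",
            stacklevel=2,
        )

    clearance = flower_diameter_mm + CLEARANCE_MARGIN_MM if flower_diameter_mm else 0.0
    content_w = max(c.n_cols * SPOT_PITCH_MM for c in categories)
    content_w = max(content_w, clearance)
    width_mm = content_w + 2 * EDGE_INSET_MM
    if min_width_mm and min_width_mm > width_mm:
        width_mm = min_width_mm

    y = EDGE_INSET_MM
    centroid_y = 0.0
    if clearance:
        centroid_y = y + clearance / 2
        y += clearance + GROUP_GAP_MM

    # spot centers in mm, origin = top-left dot center
    spot_mm: list[tuple[float, float, int, int, str]] = []
    for ci, cat in enumerate(categories):
        x0 = (width_mm - cat.n_cols * SPOT_PITCH_MM) / 2
        y += LABEL_HEIGHT_MM
        for row in range(cat.n_rows):
            for col in range(cat.n_cols):
                label = str(col) if cat.mode == "integer_range" else cat.values[col]
                spot_mm.append(
                    (
                        x0 + (col + 0.5) * SPOT_PITCH_MM,
                        y + (row + 0.5) * SPOT_PITCH_MM,
                        ci,
                        row,
                        label,
                    )
                )
        y += cat.n_rows * SPOT_PITCH_MM + GROUP_GAP_MM
    height_mm = y - GROUP_GAP_MM + EDGE_INSET_MM
    if min_height_mm and min_height_mm > height_mm:
        height_mm = min_height_mm

    # quantise the raster size, then derive exact physical size from it so the
    # pixel and millimetre aspect ratios agree identically
    k = dpi / 25.4
    width_px = int(round(width_mm * k))
    height_px = int(round(height_mm * k))
    width_mm = width_px / k
    height_mm = height_px / k

    spot_d_px = SPOT_DIAMETER_MM * k
    spots = [
        SpotGeometry(
            x=x * k,
            y=yy * k,
            width=spot_d_px,
            height=spot_d_px,
            category_index=ci,
            row_index=row,
            value_label=label,
        )
        for x, yy, ci, row, label in spot_mm
    ]

    layout = CardLayout(
        categories=list(categories),
        spots=spots,
        flower_diameter_mm=float(flower_diameter_mm),
        card_width_px=width_px,
        card_height_px=height_px,
        card_width_mm=width_mm,
        card_height_mm=height_mm,
        flower_centroid_x_px=width_px / 2,
        flower_centroid_y_px=centroid_y * k,
        dot_palette=palette,
        dot_diameter_mm=DOT_DIAMETER_MM,
        spot_diameter_mm=SPOT_DIAMETER_MM,
        flower_clearance_mm=clearance,
    )
    layout.validate()
    return layout


def _font(px: int) -> ImageFont.ImageFont:
    try:
        return ImageFont.load_default(size=px)
    except TypeError:  # older Pillow
        return ImageFont.load_default()


def render_card(
    layout: CardLayout,
    px_per_mm: float | None = None,
    marked_spots: set[int] | None = None,
) -> np.ndarray:
    """Rasterise the card as an RGB uint8 array.

    The image spans the corner-dot-center rectangle plus ``PRINT_MARGIN_MM`` on
    every side.  ``px_per_mm`` defaults to the layout's template scale (its
    dpi).  ``marked_spots`` optionally inks spots (by index) with a near-black
    disc covering ~80% of the spot area, emulating a dry-wipe marker — used by
    the synthetic fixtures; printable cards leave it None.
    """
    ppm = px_per_mm if px_per_mm is not None else layout.px_per_mm
    s = ppm / layout.px_per_mm  # template px -> render px
    margin = PRINT_MARGIN_MM * ppm
    w = int(round(layout.card_width_px * s + 2 * margin))
    h = int(round(layout.card_height_px * s + 2 * margin))
    img = Image.new("RGB", (w, h), (255, 255, 255))
    draw = ImageDraw.Draw(img)

    def to_img(x: float, y: float) -> tuple[float, float]:
        return x * s + margin, y * s + margin

    # slit indicator: from the paper's top edge down to the flower clearance
    if layout.flower_clearance_mm > 0:
        cx, cy = to_img(layout.flower_centroid_x_px, layout.flower_centroid_y_px)
        r_cl = layout.flower_clearance_mm / 2 * ppm
        lw = max(1, int(round(0.5 * ppm)))
        draw.line([(cx, 0), (cx, cy - r_cl)], fill=(0, 0, 0), width=lw)
        draw.ellipse(
            [cx - r_cl, cy - r_cl, cx + r_cl, cy + r_cl],
            outline=(200, 200, 200),
            width=max(1, int(round(0.2 * ppm))),
        )

    spot_font = _font(max(6, int(round(2.2 * ppm))))
    cat_font = _font(max(7, int(round(3.0 * ppm))))

    # category captions above each group
    for ci, cat in enumerate(layout.categories):
        group = layout.spots_for_category(ci)
        top = min(sp.y for sp in group)
        gx = min(sp.x - sp.width / 2 for sp in group)
        lx, ly = to_img(gx, top)
        draw.text(
            (lx, ly - (SPOT_PITCH_MM / 2 + LABEL_HEIGHT_MM - 0.5) * ppm),
            cat.name,
            fill=(0, 0, 0),
            font=cat_font,
        )

    outline_w = max(1, int(round(0.25 * ppm)))
    for i, sp in enumerate(layout.spots):
        cx, cy = to_img(sp.x, sp.y)
        rx = sp.width / 2 * s
        ry = sp.height / 2 * s
        draw.ellipse(
            [cx - rx, cy - ry, cx + rx, cy + ry],
            outline=(90, 90, 90),
            width=outline_w,
        )
        # value label printed light so a blank spot still reads bright
        draw.text(
            (cx, cy), sp.value_label, fill=(150, 150, 150), font=spot_font, anchor="mm"
        )
        if marked_spots and i in marked_spots:
            rm = np.sqrt(0.8) * rx
            g = INK_GRAY
            draw.ellipse(
                [cx - rm, cy - rm, cx + rm, cy + rm], fill=(g, g, g)
            )

    # fiducial corner dots, centered exactly on the dot-center rectangle corners
    body = PALETTE_RGB[layout.dot_palette]
    rd = layout.dot_diameter_mm / 2 * ppm
    rc = rd / 3
    corners = {
        "top_left": (0.0, 0.0),
        "top_right": (float(layout.card_width_px), 0.0),
        "bottom_left": (0.0, float(layout.card_height_px)),
        "bottom_right": (float(layout.card_width_px), float(layout.card_height_px)),
    }
    for name, (tx, ty) in corners.items():
        cx, cy = to_img(tx, ty)
        draw.ellipse([cx - rd, cy - rd, cx + rd, cy + rd], fill=body)
        cc = CENTER_RGB[layout.corner_center_colors[name]]
        draw.ellipse([cx - rc, cy - rc, cx + rc, cy + rc], fill=cc)

    return np.asarray(img)


def save_card(layout: CardLayout, path: str | Path, dpi: int | None = None) -> Path:
    """Render and save the card (TIFF or PNG by extension) with dpi metadata."""
    path = Path(path)
    ppm = (dpi / 25.4) if dpi else layout.px_per_mm
    arr = render_card(layout, px_per_mm=ppm)
    img = Image.fromarray(arr)
    dots_per_inch = ppm * 25.4
    img.save(path, dpi=(dots_per_inch, dots_per_inch))
    return path
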