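"""Card data model and the configuration file linking printed cards to the detector.

A card is described by a :class:`CardLayout`: an ordered list of categories
(:class:`CategorySpec`), the geometry of every markable spot
(:class:`SpotGeometry`), the four fiducial corner dots and the physical size of
the rectangle they span.  The layout is serialised to a versioned, human-readable
``key=value`` text file (extension ``.spotcard.cfg``) written next to the printed
card image; the detector reads it back to locate spots and compute scale.

Coordinate convention: template pixels, origin at the *top-left corner-dot
center*, x rightwards, y downwards.  ``card_width_mm``/``card_height_mm`` are the
physical dimensions of the corner-dot-center rectangle, so
``card_width_mm / card_width_px`` is the template's mm-per-pixel scale.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "CategorySpec",
    "SpotGeometry",
    "CardLayout",
    "ConfigError",
    "parse_category_input",
    "write_config",
    "read_config",
    "CONFIG_VERSION",
]

CONFIG_VERSION = 1

#: canonical corner-center colors; detection orients the card by these.
CORNER_CENTER_COLORS = {
    "top_left": "red",
    "top_right": "green",
    "bottom_left": "white",
    "bottom_right": "black",
}

# soft limits from field practicality, not hard errors
SOFT_MAX_CATEGORIES = 9
SOFT_MAX_VALUES = 15

_RANGE_RE = re.compile(r"^0\s*[-–]\s*(9+)$")


class ConfigError(ValueError):
    """Raised for invalid category input, invalid layouts or bad config files."""


@dataclass(frozen=True)
class CategorySpec:
    """One category of annotation spots.

    ``explicit`` mode carries an ordered list of value labels, one spot each.
    ``integer_range`` mode encodes integers 0..range_max (range_max = 10**k - 1)
    as k rows of ten digit spots, most-significant row first.
    """

    name: str
    mode: str  # "explicit" | "integer_range"
    values: tuple[str, ...] = ()
    range_max: int = 0

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ConfigError("category name must be non-empty")
        if self.mode == "explicit":
            if len(self.values) < 2:
                raise ConfigError(
                    f"category {self.name!r}: a single value is not a markable "
                    "choice; give at least two values"
                )
            if any(not v for v in self.values):
                raise ConfigError(f"category {self.name!r}: empty value label")
            if len(set(self.values)) != len(self.values):
                raise ConfigError(f"category {self.name!r}: duplicate value labels")
            if len(self.values) > SOFT_MAX_VALUES:
                warnings.warn(
                    f"category {self.name!r} has {len(self.values)} values; cards "
                    f"beyond ~{SOFT_MAX_VALUES} values become impractically large",
                    stacklevel=2,
                )
        elif self.mode == "integer_range":
            k = self.n_rows
            if k < 1 or self.range_max != 10**k - 1:
                raise ConfigError(
                    f"category {self.name!r}: integer range must end at 9, 99, "
                    f"999, ... (got {self.range_max})"
                )
        else:
            raise ConfigError(f"unknown category mode {self.mode!r}")

    @property
    def n_rows(self) -> int:
        """Number of spot rows this category occupies."""
        if self.mode == "explicit":
            return 1
        return max(1, len(str(self.range_max)))

    @property
    def n_cols(self) -> int:
        return len(self.values) if self.mode == "explicit" else 10

    @property
    def n_spots(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True)
class SpotGeometry:
    """Position and size of one spot, in template pixels."""

    x: float
    y: float
    width: float
    height: float
    category_index: int
    row_index: int
    value_label: str


@dataclass
class CardLayout:
    """Complete geometric and semantic description of one card design."""

    categories: list[CategorySpec]
    spots: list[SpotGeometry]
    flower_diameter_mm: float
    card_width_px: int
    card_height_px: int
    card_width_mm: float
    card_height_mm: float
    flower_centroid_x_px: float
    flower_centroid_y_px: float
    dot_palette: str = "blue"
    dot_diameter_mm: float = 10.0
    spot_diameter_mm: float = 6.0
    flower_clearance_mm: float = 0.0
    corner_center_colors: dict[str, str] = field(
        default_factory=lambda: dict(CORNER_CENTER_COLORS)
    )

    # -- derived ----------------------------------------------------------
    @property
    def px_per_mm(self) -> float:
        return self.card_width_px / self.card_width_mm

    @property
    def aspect_ratio(self) -> float:
        """Theoretical width/height ratio of the corner-dot rectangle."""
        return self.card_width_mm / self.card_height_mm

    def spots_for_category(self, index: int) -> list[SpotGeometry]:
        return [s for s in self.spots if s.category_index == index]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Re-check every structural invariant; raise :class:`ConfigError`."""
        if not self.categories:
            raise ConfigError("layout has no categories")
        if self.flower_diameter_mm < 0:
            raise ConfigError("flower_diameter_mm must be >= 0")
        if self.card_width_px <= 0 or self.card_height_px <= 0:
            raise ConfigError("card pixel dimensions must be positive")
        px_ratio = self.card_width_px / self.card_height_px
        mm_ratio = self.card_width_mm / self.card_height_mm
        if abs(px_ratio - mm_ratio) > 1e-6 * mm_ratio:
            raise ConfigError(
                f"pixel aspect ratio {px_ratio:.8f} disagrees with physical "
                f"aspect ratio {mm_ratio:.8f}"
            )
        if abs(self.flower_centroid_x_px - self.card_width_px / 2) > 1e-6:
            raise ConfigError(
                "flower centroid X must be half the card width "
                f"(got {self.flower_centroid_x_px}, width {self.card_width_px})"
            )
        if len(set(self.corner_center_colors.values())) != 4:
            raise ConfigError("corner center colors must be pairwise distinct")
        if self.dot_palette not in ("blue", "pink"):
            raise ConfigError(f"unknown dot palette {self.dot_palette!r}")

        expected = sum(c.n_spots for c in self.categories)
        if len(self.spots) != expected:
            raise ConfigError(
                f"layout has {len(self.spots)} spots; categories require {expected}"
            )
        for s in self.spots:
            if not (0 < s.x < self.card_width_px and 0 < s.y < self.card_height_px):
                raise ConfigError(
                    f"spot {s.value_label!r} at ({s.x:.1f},{s.y:.1f}) lies outside "
                    "the corner-dot rectangle"
                )
        # pairwise overlap: spots are on a regular grid, so a simple O(n^2)
        # center-distance check is fine at these sizes
        for i, a in enumerate(self.spots):
            for b in self.spots[i + 1 :]:
                if (
                    abs(a.x - b.x) < (a.width + b.width) / 2
                    and abs(a.y - b.y) < (a.height + b.height) / 2
                ):
                    raise ConfigError(
                        f"spots {a.value_label!r} and {b.value_label!r} overlap"
                    )
        if self.flower_clearance_mm > 0:
            r = self.flower_clearance_mm / 2 * self.px_per_mm
            for s in self.spots:
                d = math.hypot(
                    s.x - self.flower_centroid_x_px, s.y - self.flower_centroid_y_px
                )
                if d < r:
                    raise ConfigError(
                        f"spot {s.value_label!r} intrudes into the flower clearance"
                    )


def parse_category_input(name: str, value_string: str) -> CategorySpec:
    """Parse a user-entered category description.

    A comma-separated list (``"A, B, C, D"``) becomes an explicit category; a
    string ``0-9``, ``0-99``, ``0-999``, ... becomes an integer-range category
    whose digits are marked row by row, most significant first.
    """
    if not name or not name.strip():
        raise ConfigError("category name must be non-empty")
    if not value_string or not value_string.strip():
        raise ConfigError(f"category {name!r}: value string must be non-empty")
    text = value_string.strip()
    m = _RANGE_RE.match(text)
    if m:
        return CategorySpec(
            name=name.strip(), mode="integer_range", range_max=int(m.group(1))
        )
    if "-" in text and "," not in text:
        raise ConfigError(
            f"category {name!r}: range {text!r} must start at 0 and end in all "
            "9s (e.g. 0-99)"
        )
    labels = tuple(v.strip() for v in text.split(","))
    return CategorySpec(name=name.strip(), mode="explicit", values=labels)


# ---------------------------------------------------------------------------
# configuration file I/O
# ---------------------------------------------------------------------------

_NO_FLOWER = "no flower"


def _fmt_float(x: float) -> str:
    return repr(float(x))


def write_config(layout: CardLayout, path: str | Path) -> Path:
    """Write ``layout`` as a versioned key=value text file (loss-free)."""
    layout.validate()
    path = Path(path)
    lines = [
        f"spotcard_config_version={CONFIG_VERSION}",
        f"card_width_px={layout.card_width_px}",
        f"card_height_px={layout.card_height_px}",
        f"card_width_mm={_fmt_float(layout.card_width_mm)}",
        f"card_height_mm={_fmt_float(layout.card_height_mm)}",
        "flower_diameter_mm="
        + (_NO_FLOWER if layout.flower_diameter_mm == 0 else _fmt_float(layout.flower_diameter_mm)),
        f"flower_clearance_mm={_fmt_float(layout.flower_clearance_mm)}",
        f"flower_centroid_x_px={_fmt_float(layout.flower_centroid_x_px)}",
        f"flower_centroid_y_px={_fmt_float(layout.flower_centroid_y_px)}",
        f"dot_palette={layout.dot_palette}",
        f"dot_diameter_mm={_fmt_float(layout.dot_diameter_mm)}",
        f"spot_diameter_mm={_fmt_float(layout.spot_diameter_mm)}",
        "corner_center_colors="
        + ",".join(f"{k}:{v}" for k, v in sorted(layout.corner_center_colors.items())),
        f"n_categories={len(layout.categories)}",
    ]
    for i, cat in enumerate(layout.categories):
        lines.append(f"category_{i}_name={cat.name}")
        lines.append(f"category_{i}_mode={cat.mode}")
        if cat.mode == "explicit":
            lines.append(f"category_{i}_values=" + ",".join(cat.values))
        else:
            lines.append(f"category_{i}_range_max={cat.range_max}")
    lines.append(f"n_spots={len(layout.spots)}")
    for i, s in enumerate(layout.spots):
        lines.append(
            f"spot_{i}="
            + ",".join(
                [
                    _fmt_float(s.x),
                    _fmt_float(s.y),
                    _fmt_float(s.width),
                    _fmt_float(s.height),
                    str(s.category_index),
                    str(s.row_index),
                    s.value_label,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _require(kv: dict[str, str], key: str) -> str:
    if key not in kv:
        raise ConfigError(f"configuration file is missing key {key!r}")
    return kv[key]


def read_config(path: str | Path) -> CardLayout:
    """Read a configuration file back into a validated :class:`CardLayout`."""
    path = Path(path)
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path.name}:{lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        kv[key.strip()] = value

    version = int(_require(kv, "spotcard_config_version"))
    if version != CONFIG_VERSION:
        raise ConfigError(
            f"configuration version {version} not supported (expected {CONFIG_VERSION})"
        )

    flower_raw = _require(kv, "flower_diameter_mm")
    flower_mm = 0.0 if flower_raw.strip() == _NO_FLOWER else float(flower_raw)

    categories = []
    for i in range(int(_require(kv, "n_categories"))):
        mode = _require(kv, f"category_{i}_mode")
        name = _require(kv, f"category_{i}_name")
        if mode == "explicit":
            values = tuple(_require(kv, f"category_{i}_values").split(","))
            categories.append(CategorySpec(name=name, mode=mode, values=values))
        else:
            categories.append(
                CategorySpec(
                    name=name,
                    mode=mode,
                    range_max=int(_require(kv, f"category_{i}_range_max")),
                )
            )

    spots = []
    for i in range(int(_require(kv, "n_spots"))):
        parts = _require(kv, f"spot_{i}").split(",")
        if len(parts) != 7:
            raise ConfigError(f"malformed spot record spot_{i}")
        spots.append(
            SpotGeometry(
                x=float(parts[0]),
                y=float(parts[1]),
                width=float(parts[2]),
                height=float(parts[3]),
                category_index=int(parts[4]),
                row_index=int(parts[5]),
                value_label=parts[6],
            )
        )

    colors = dict(
        item.split(":", 1) for item in _require(kv, "corner_center_colors").split(",")
    )
    layout = CardLayout(
        categories=categories,
        spots=spots,
        flower_diameter_mm=flower_mm,
        card_width_px=int(_require(kv, "card_width_px")),
        card_height_px=int(_require(kv, "card_height_px")),
        card_width_mm=float(_require(kv, "card_width_mm")),
        card_height_mm=float(_require(kv, "card_height_mm")),
        flower_centroid_x_px=float(_require(kv, "flower_centroid_x_px")),
        flower_centroid_y_px=float(_require(kv, "flower_centroid_y_px")),
        dot_palette=_require(kv, "dot_palette"),
        dot_diameter_mm=float(_require(kv, "dot_diameter_mm")),
        spot_diameter_mm=float(_require(kv, "spot_diameter_mm")),
        flower_clearance_mm=float(_require(kv, "flower_clearance_mm")),
        corner_center_colors=colors,
    )
    layout.validate()
    return layout
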