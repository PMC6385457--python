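"""EXIF extraction and batch CSV output.

Each photograph yields exactly one CSV row — filename, capture date/time, GPS
position, one column per card category, flower area/perimeter and an error
column.  A failed image still produces its row (error code filled, value cells
blank) and never aborts the batch, so the row count always equals the image
count.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import measure as _measure
from .card_spec import CardLayout, read_config
from .detect import DetectionError, analyse_image, DEFAULT_MARK_THRESHOLD

__all__ = [
    "RecordRow",
    "ExifData",
    "extract_exif",
    "dms_to_decimal",
    "decimal_to_dms",
    "write_results",
    "run_batch",
    "IMAGE_EXTENSIONS",
]

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".jpg", ".jpeg", ".tif", ".tiff", ".png"}

_TAG_DATETIME = 0x0132
_TAG_EXIF_IFD = 0x8769
_TAG_DT_ORIGINAL = 0x9003
_TAG_GPS_IFD = 0x8825


@dataclass
class ExifData:
    datetime: str = ""  # ISO-8601 local time, or blank
    latitude: float | None = None
    longitude: float | None = None
    altitude: float | None = None


@dataclass
class RecordRow:
    filename: str
    exif: ExifData = field(default_factory=ExifData)
    values: dict[str, str] = field(default_factory=dict)
    area_mm2: float | None = None
    perimeter_mm: float | None = None
    error: str = ""


def dms_to_decimal(dms, ref: str) -> float:
    """Degrees/minutes/seconds rationals + hemisphere ref -> signed decimal."""
    deg, minutes, seconds = (float(v) for v in dms)
    value = deg + minutes / 60.0 + seconds / 3600.0
    if str(ref).upper() in ("S", "W"):
        value = -value
    return value

def decimal_to_dms(value: float) -> tuple[tuple[int, int, float], str]:
    """Signed decimal degrees -> ((d, m, s), positive-hemisphere flag).

    Returns the magnitude split into degrees, minutes, seconds and whether the
    input was non-negative (caller picks N/S or E/W accordingly).
    """
    positive = value >= 0
    v = abs(value)
    d = int(v)
    m = int((v - d) * 60)
    s = (v - d - m / 60.0) * 3600.0
    return (d, m, s), positive


def _iso(exif_dt: str) -> str:
    """EXIF 'YYYY:MM:DD HH:MM:SS' -> ISO-8601 'YYYY-MM-DDTHH:MM:SS'."""
    try:
        date, _, time = exif_dt.strip().partition(" ")
        y, mo, d = date.split(":")
        return f"{y}-{mo}-{d}T{time}" if time else f"{y}-{mo}-{d}"
    except (ValueError, AttributeError):
        return exif_dt.strip()


def extract_exif(path: str | Path) -> ExifData:
    """Read capture time and GPS position from a photograph.

    Prefers DateTimeOriginal over DateTime; GPS rationals are converted to
    signed decimal degrees via the N/S and E/W reference tags, altitude signed
    by its reference byte.  Absent tags give blanks, never an error.
    """
    out = ExifData()
    with Image.open(path) as img:
        exif = img.getexif()
        if not exif:
            return out
        dt = exif.get_ifd(_TAG_EXIF_IFD).get(_TAG_DT_ORIGINAL) or exif.get(
            _TAG_DATETIME
        )
        if dt:
            out.datetime = _iso(str(dt))
        gps = exif.get_ifd(_TAG_GPS_IFD)
        if gps:
            if 2 in gps and 1 in gps:
                out.latitude = dms_to_decimal(gps[2], gps[1])
            if 4 in gps and 3 in gps:
                out.longitude = dms_to_decimal(gps[4], gps[3])
            if 6 in gps:
                alt = float(gps[6])
                ref = gps.get(5, b"\x00")
                ref_val = ref[0] if isinstance(ref, (bytes, bytearray)) else int(ref)
                out.altitude = -alt if ref_val == 1 else alt
    return out


def _fmt(x: float | None, nd: int = 6) -> str:
    return "" if x is None else f"{round(x, nd):g}"


def write_results(
    rows: list[RecordRow], path: str | Path, layout: CardLayout
) -> Path:
    """Write the batch results as an RFC-4180 CSV (UTF-8, LF line endings)."""
    path = Path(path)
    header = (
        ["filename", "datetime", "latitude", "longitude", "altitude"]
        + [c.name for c in layout.categories]
        + ["area_mm2", "perimeter_mm", "error"]
    )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(
                [
                    row.filename,
                    row.exif.datetime,
                    _fmt(row.exif.latitude),
                    _fmt(row.exif.longitude),
                    _fmt(row.exif.altitude, 2),
                ]
                + [row.values.get(c.name, "") for c in layout.categories]
                + [_fmt(row.area_mm2, 3), _fmt(row.perimeter_mm, 3), row.error]
            )
    return path


def process_image(
    path: Path,
    layout: CardLayout,
    mark_threshold: float = DEFAULT_MARK_THRESHOLD,
    measure_flower: bool = False,
    save_crops: Path | None = None,
) -> RecordRow:
    """Process one photograph into a :class:`RecordRow` (never raises)."""
    row = RecordRow(filename=path.name)
    try:
        row.exif = extract_exif(path)
    except Exception as exc:  # unreadable file
        row.error = f"UNREADABLE_IMAGE: {exc}"
        return row
    try:
        with Image.open(path) as img:
            arr = np.asarray(img.convert("RGB"))
        detected, reading = analyse_image(arr, layout, mark_threshold)
        row.values = reading.values
        if measure_flower and layout.flower_diameter_mm > 0:
            try:
                scale = _measure.compute_scale(detected, layout)
                fm = _measure.segment_flower(detected.rectified, layout, scale)
            except DetectionError as exc:
                # soft failure: keep the decoded values, blank the measurements
                row.error = exc.code
                return row
            row.area_mm2 = fm.area_mm2
            row.perimeter_mm = fm.perimeter_mm
            if save_crops is not None:
                save_crops.mkdir(parents=True, exist_ok=True)
                stem = path.stem
                Image.fromarray(
                    (np.clip(fm.flower_crop, 0, 1) * 255).astype(np.uint8)
                ).save(save_crops / f"{stem}_flower.png")
                Image.fromarray(
                    (fm.mask * 255).astype(np.uint8)
                ).save(save_crops / f"{stem}_floodfill.png")
    except DetectionError as exc:
        row.error = exc.code
        logger.info("%s: %s (%s)", path.name, exc.code, exc)
    except Exception as exc:
        row.error = f"UNREADABLE_IMAGE: {exc}"
        logger.info("%s: unreadable (%s)", path.name, exc)
    return row


def run_batch(
    config_path: str | Path,
    image_dir: str | Path,
    out_csv: str | Path,
    mark_threshold: float = DEFAULT_MARK_THRESHOLD,
    measure_flower: bool = False,
    save_crops: str | Path | None = None,
) -> list[RecordRow]:
    """Process every image in ``image_dir`` (lexicographic order) into a CSV.

    Per-image failures are recorded in the error column and processing
    continues; a bad configuration path aborts before any image is touched.
    """
    layout = read_config(config_path)  # aborts the batch if invalid
    image_dir = Path(image_dir)
    paths = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if not paths:
        logger.warning("no images found in %s", image_dir)
    rows = [
        process_image(
            p,
            layout,
            mark_threshold=mark_threshold,
            measure_flower=measure_flower,
            save_crops=Path(save_crops) if save_crops else None,
        )
        for p in paths
    ]
    write_results(rows, out_csv, layout)
    n_err = sum(1 for r in rows if r.error)
    codes = Counter(r.error.split(":")[0] for r in rows if r.error)
    logger.info(
        "processed %d images: %d ok, %d errors %s",
        len(rows),
        len(rows) - n_err,
        n_err,
        dict(codes),
    )
    return rows
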