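"""EXIF extraction, GPS conversion and batch CSV output."""

import csv

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from PIL import Image

from spotmark.card_spec import write_config
from spotmark.metadata_io import (
    ExifData,
    RecordRow,
    decimal_to_dms,
    dms_to_decimal,
    extract_exif,
    run_batch,
    write_results,
)
from spotmark import synthetic_fixtures as sf
from .conftest import FIG1_MARKS


class TestGpsConversion:
    def test_known_position(self):
        # 52 deg 12' 18" N, 0 deg 07' 30" E
        assert dms_to_decimal((52, 12, 18), "N") == pytest.approx(52.205)
        assert dms_to_decimal((0, 7, 30), "E") == pytest.approx(0.125)

    def test_southern_western_hemispheres_negative(self):
        assert dms_to_decimal((33, 51, 54), "S") == pytest.approx(-33.865)
        assert dms_to_decimal((70, 40, 0), "W") == pytest.approx(-70.666667)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=-179.999, max_value=179.999))
    def test_round_trip_within_microdegree(self, value):
        (d, m, s), positive = decimal_to_dms(value)
        back = dms_to_decimal((d, m, s), "N" if positive else "S")
        assert back == pytest.approx(value, abs=1e-6)


class TestExtractExif:
    def test_injected_tags_round_trip(self, fig1_layout, tmp_path):
        spec = sf.FixtureSpec(
            layout=fig1_layout,
            marks=dict(FIG1_MARKS),
            exif=sf.ExifFixture(
                datetime="2023:06:01 10:30:00",
                latitude=52.205,
                longitude=-0.125,
                altitude=-3.5,
            ),
        )
        path, _ = sf.save_fixture(spec, tmp_path / "img.jpg")
        data = extract_exif(path)
        assert data.datetime == "2023-06-01T10:30:00"
        assert data.latitude == pytest.approx(52.205, abs=1e-6)
        assert data.longitude == pytest.approx(-0.125, abs=1e-6)
        assert data.altitude == pytest.approx(-3.5, abs=1e-3)

    def test_png_without_exif_yields_blanks(self, tmp_path):
        p = tmp_path / "plain.png"
        Image.fromarray(np.full((16, 16, 3), 128, np.uint8)).save(p)
        data = extract_exif(p)
        assert data == ExifData()


class TestWriteResults:
    def test_header_only_for_empty_batch(self, plain_layout, tmp_path):
        p = write_results([], tmp_path / "out.csv", plain_layout)
        lines = p.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("filename,datetime,latitude")
        assert "Variety" in lines[0] and "Plant" in lines[0]

    def test_values_with_commas_are_quoted(self, plain_layout, tmp_path):
        row = RecordRow(filename="a,b.jpg", values={"Variety": "B"})
        p = write_results([row], tmp_path / "out.csv", plain_layout)
        with open(p, newline="") as fh:
            parsed = list(csv.reader(fh))
        assert parsed[1][0] == "a,b.jpg"

    def test_error_row_keeps_blank_value_cells(self, plain_layout, tmp_path):
        rows = [
            RecordRow(filename="ok.jpg", values={"Variety": "A", "Flower": "1", "Plant": "2"}),
            RecordRow(filename="bad.jpg", error="CORNERS_NOT_FOUND"),
        ]
        p = write_results(rows, tmp_path / "out.csv", plain_layout)
        with open(p, newline="") as fh:
            parsed = list(csv.DictReader(fh))
        assert parsed[1]["Variety"] == ""
        assert parsed[1]["error"] == "CORNERS_NOT_FOUND"
        assert parsed[0]["error"] == ""


@pytest.fixture(scope="module")
def batch_dir(tmp_path_factory, fig1_layout):
    d = tmp_path_factory.mktemp("batch")
    cfg = write_config(fig1_layout, d / "card.spotcard.cfg")
    sf.save_fixture(
        sf.FixtureSpec(layout=fig1_layout, marks=dict(FIG1_MARKS),
                       exif=sf.ExifFixture()),
        d / "img0.jpg",
    )
    sf.save_fixture(
        sf.FixtureSpec(layout=fig1_layout, marks={0: "C", 1: "1", 2: 4},
                       rotation_deg=77.0),
        d / "img1.png",
    )
    (d / "img2.jpg").write_bytes(b"this is not an image")
    sf.save_fixture(
        sf.FixtureSpec(layout=fig1_layout, marks=dict(FIG1_MARKS),
                       occlude_corner="BR"),
        d / "img3.jpg",
    )
    return d, cfg


class TestRunBatch:
    def test_row_per_image_despite_failures(self, batch_dir, tmp_path):
        d, cfg = batch_dir
        out = tmp_path / "results.csv"
        rows = run_batch(cfg, d, out)
        assert len(rows) == 4
        assert [r.filename for r in rows] == ["img0.jpg", "img1.png", "img2.jpg", "img3.jpg"]
        assert rows[0].values["Variety"] == "B" and rows[0].error == ""
        assert rows[1].values["Plant"] == "4"
        assert rows[2].error.startswith("UNREADABLE_IMAGE")
        assert rows[3].error == "CORNERS_NOT_FOUND"

    def test_exif_lands_in_rows(self, batch_dir, tmp_path):
        d, cfg = batch_dir
        rows = run_batch(cfg, d, tmp_path / "r.csv")
        assert rows[0].exif.latitude == pytest.approx(52.205, abs=1e-4)
        assert rows[1].exif.datetime == ""  # PNG fixture carries no EXIF

    def test_rerun_is_byte_identical(self, batch_dir, tmp_path):
        d, cfg = batch_dir
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        run_batch(cfg, d, p1)
        run_batch(cfg, d, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_directory_yields_header_only(self, fig1_layout, tmp_path):
        cfg = write_config(fig1_layout, tmp_path / "card.spotcard.cfg")
        empty = tmp_path / "imgs"
        empty.mkdir()
        out = tmp_path / "out.csv"
        rows = run_batch(cfg, empty, out)
        assert rows == []
        assert len(out.read_text().splitlines()) == 1

    def test_bad_config_aborts(self, tmp_path):
        with pytest.raises(Exception):
            run_batch(tmp_path / "missing.cfg", tmp_path, tmp_path / "out.csv")
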