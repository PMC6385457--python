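"""Corner-dot detection, orientation, validation and spot decoding."""

import numpy as np
import pytest
from PIL import Image, ImageDraw

from spotmark.card_generate import layout_card, marks_to_spot_indices
from spotmark.detect import (
    AMBIGUOUS,
    MISSING,
    DetectionError,
    adjust_contrast,
    analyse_image,
    decode,
    find_corner_dots,
    identify_orientation,
)
from spotmark import synthetic_fixtures as sf
from .conftest import FIG1_MARKS


class TestFindCornerDots:
    def test_finds_exactly_four(self, frontal_fixture):
        arr, _ = frontal_fixture
        regions = find_corner_dots(adjust_contrast(arr), "blue")
        assert len(regions) == 4

    def test_small_speck_excluded_by_largest_four_rule(self, fig1_layout):
        arr, truth = sf.render_fixture(
            sf.FixtureSpec(layout=fig1_layout, marks=dict(FIG1_MARKS), distractor_px=10)
        )
        detected, reading = analyse_image(arr, fig1_layout)
        assert reading.values == truth["expected_values"]

    def test_occluded_corner_raises(self, fig1_layout):
        arr, _ = sf.render_fixture(
            sf.FixtureSpec(layout=fig1_layout, marks=dict(FIG1_MARKS), occlude_corner="TL")
        )
        with pytest.raises(DetectionError) as err:
            analyse_image(arr, fig1_layout)
        assert err.value.code == "CORNERS_NOT_FOUND"

    def test_large_distractor_caught_by_downstream_checks(self, fig1_layout):
        arr, _ = sf.render_fixture(
            sf.FixtureSpec(layout=fig1_layout, marks=dict(FIG1_MARKS), distractor_px=160)
        )
        with pytest.raises(DetectionError) as err:
            analyse_image(arr, fig1_layout)
        assert err.value.code in (
            "CENTERS_UNRESOLVED",
            "DIAGONAL_MISMATCH",
            "ASPECT_MISMATCH",
            "ORIENTATION_CHECK_FAILED",
        )


def _four_dot_image(center_colors):
    """A minimal synthetic photo: four blue dots with given center colors."""
    img = Image.new("RGB", (400, 400), (200, 200, 200))
    draw = ImageDraw.Draw(img)
    positions = [(80, 80), (320, 80), (80, 320), (320, 320)]
    for (x, y), color in zip(positions, center_colors):
        draw.ellipse([x - 40, y - 40, x + 40, y + 40], fill=(30, 60, 220))
        draw.ellipse([x - 13, y - 13, x + 13, y + 13], fill=color)
    return np.asarray(img)


class TestIdentifyOrientation:
    def test_upright_square_has_zero_rotation(self):
        arr = _four_dot_image(
            [(220, 30, 30), (30, 160, 40), (255, 255, 255), (10, 10, 10)]
        )
        adjusted = adjust_contrast(arr)
        corners, rotation = identify_orientation(
            adjusted, find_corner_dots(adjusted, "blue")
        )
        assert rotation == pytest.approx(0.0, abs=0.5)
        assert corners["TL"].center_color == "red"
        assert corners["BR"].center_color == "black"

    def test_duplicate_center_color_unresolved(self):
        arr = _four_dot_image(
            [(220, 30, 30), (220, 30, 30), (255, 255, 255), (10, 10, 10)]
        )
        adjusted = adjust_contrast(arr)
        with pytest.raises(DetectionError) as err:
            identify_orientation(adjusted, find_corner_dots(adjusted, "blue"))
        assert err.value.code == "CENTERS_UNRESOLVED"


class TestRectifyAndValidate:
    def test_frontal_passes_all_checks(self, frontal_analysis):
        detected, reading, truth = frontal_analysis
        assert detected.diag_ratio > 0.995
        assert detected.aspect_error < 0.01
        assert abs(detected.rotation_deg) < 1.0
        assert reading.values == truth["expected_values"]

    def test_mm_per_px_matches_render_scale(self, frontal_analysis):
        detected, _, truth = frontal_analysis
        assert detected.mm_per_px == pytest.approx(1 / truth["px_per_mm"], rel=0.01)

    @pytest.mark.parametrize("rotation", [0, 90, 180, 270])
    def test_rotation_invariance(self, fig1_layout, rotation):
        arr, truth = sf.render_fixture(
            sf.FixtureSpec(
                layout=fig1_layout, marks=dict(FIG1_MARKS), rotation_deg=float(rotation)
            )
        )
        detected, reading = analyse_image(arr, fig1_layout)
        assert reading.values == truth["expected_values"]

    def test_diag_tilt_18_passes_25_fails(self, fig1_layout):
        arr, _ = sf.render_fixture(
            sf.FixtureSpec(
                layout=fig1_layout, marks=dict(FIG1_MARKS),
                tilt_deg=18.0, tilt_axis="diag",
            )
        )
        detected, _ = analyse_image(arr, fig1_layout)
        assert detected.diag_ratio >= 0.95
        arr, _ = sf.render_fixture(
            sf.FixtureSpec(
                layout=fig1_layout, marks=dict(FIG1_MARKS),
                tilt_deg=25.0, tilt_axis="x",
            )
        )
        with pytest.raises(DetectionError) as err:
            analyse_image(arr, fig1_layout)
        assert err.value.code == "ASPECT_MISMATCH"

    @pytest.mark.parametrize("tilt", [5, 10, 15])
    def test_orthographic_diag_ratio_matches_cos_tilt(self, tilt):
        # perpendicular diagonals (square card) under orthographic projection
        square = layout_card(
            sf.fig1_categories(), flower_diameter_mm=20,
            min_width_mm=110, min_height_mm=110,
        )
        arr, _ = sf.render_fixture(
            sf.FixtureSpec(
                layout=square, marks=dict(FIG1_MARKS), tilt_deg=float(tilt),
                tilt_axis="diag", camera_distance_factor=None,
            )
        )
        detected, _ = analyse_image(arr, square)
        assert detected.diag_ratio == pytest.approx(
            np.cos(np.radians(tilt)), abs=0.005
        )


class TestReadAndDecode:
    def test_marked_spots_read_dark_blank_read_bright(self, frontal_analysis, fig1_layout):
        _, reading, _ = frontal_analysis
        inked = marks_to_spot_indices(fig1_layout, FIG1_MARKS)
        for i, mean in enumerate(reading.spot_means):
            if i in inked:
                assert mean < 70, f"marked spot {i} read {mean}"
            else:
                assert mean > 170, f"blank spot {i} read {mean}"

    def test_decode_soft_statuses(self, fig1_layout):
        # synthetic per-spot means: Variety double-marked, Flower blank,
        # Plant marked 3 in tens row and 7 in units row
        means = [255.0] * len(fig1_layout.spots)
        for i, s in enumerate(fig1_layout.spots):
            if s.category_index == 0 and s.value_label in ("A", "B"):
                means[i] = 10.0
            if s.category_index == 2 and (s.row_index, s.value_label) in (
                (0, "3"),
                (1, "7"),
            ):
                means[i] = 10.0
        reading = decode(means, fig1_layout)
        assert reading.values == {
            "Variety": AMBIGUOUS,
            "Flower": MISSING,
            "Plant": "37",
        }

    def test_unmarked_card_reads_all_missing(self, fig1_layout):
        arr, _ = sf.render_fixture(sf.FixtureSpec(layout=fig1_layout, marks={}))
        _, reading = analyse_image(arr, fig1_layout)
        assert all(v == MISSING for v in reading.values.values())

    def test_pink_palette_under_illumination_gradient(self):
        layout = layout_card(
            sf.fig1_categories(), flower_diameter_mm=20, palette="pink"
        )
        arr, truth = sf.render_fixture(
            sf.FixtureSpec(
                layout=layout, marks={0: "D", 1: "3", 2: 90},
                rotation_deg=200.0, illumination_gradient=0.2,
            )
        )
        _, reading = analyse_image(arr, layout)
        assert reading.values == truth["expected_values"]
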