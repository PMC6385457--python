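import numpy as np
import pytest

from spotmark.card_generate import layout_card
from spotmark.detect import analyse_image
from spotmark import synthetic_fixtures as sf

FIG1_MARKS = {0: "B", 1: "2", 2: 37}


@pytest.fixture(scope="session")
def fig1_layout():
    """Three-category card: Variety A-D, Flower 1-3, Plant 0-99, 20 mm flower."""
    return layout_card(sf.fig1_categories(), flower_diameter_mm=20)


@pytest.fixture(scope="session")
def plain_layout():
    """Same categories, no flower: groups stacked vertically."""
    return layout_card(sf.fig1_categories(), flower_diameter_mm=0)


@pytest.fixture(scope="session")
def frontal_fixture(fig1_layout):
    """A clean frontal photograph of the marked card, plus its ground truth."""
    spec = sf.FixtureSpec(layout=fig1_layout, marks=dict(FIG1_MARKS))
    arr, truth = sf.render_fixture(spec)
    return arr, truth


@pytest.fixture(scope="session")
def frontal_analysis(frontal_fixture, fig1_layout):
    """Detection + reading of the frontal fixture (shared to save renders)."""
    arr, truth = frontal_fixture
    detected, reading = analyse_image(arr, fig1_layout)
    return detected, reading, truth
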