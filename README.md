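# spotmark

Optical-mark-recognition annotation cards for field photography of plants.

When photographing biological samples in the field — flowers in a pollinator
experiment, say — you usually need to record sample number, replicate,
cultivar and the like alongside each picture. Writing this down and
transcribing it later is slow and error-prone, and separates the data from the
image. `spotmark` instead puts the data *in* the image: it designs small
reusable cards carrying grids of markable spots (filled in the field with a
dry-wipe pen) and four colored fiducial corner dots, then batch-reads
photographs of those cards — decoding the marks, pulling capture date/time and
GPS position from EXIF, and measuring the photographed flower's area and
perimeter in real millimetres, using the card's known physical size as the
scale reference. One pass, no transcription.

## How it works

**Card design.** A card is a list of categories. A category is either an
explicit value list (`Variety = A, B, C, D` — one spot per value) or an
integer range (`Plant = 0–99` — one row of digit spots 0–9 per decimal place,
most-significant row first; 532 is recorded by marking 5 in the hundreds row,
3 in the tens row, 2 in the units row, leading zeros marked explicitly). Four
corner dots (blue by default; pink for photographing blue samples) each carry
a small center disc — red top-left, green top-right, white bottom-left, black
bottom-right — which lets the reader recover the card's orientation from any
rotation. With a flower-diameter preset, a spot-free circular clearance is
kept for the flower stem slit, backed by matt black card. A `.spotcard.cfg`
text file records the full geometry for the reader.

**Reading.** For each photograph: contrast-stretch; threshold the fiducial
color in HSV; take the four largest blobs as the corner dots; classify the
center discs (nearest reference color in CIE Lab); rotate rigidly so red is
top-left (angle from the red→black and green→white diagonal directions) and
crop to the dot centers. Three geometric checks guard against excessive
out-of-plane tilt or a mislocated card: opposing diagonals within 5% of each
other (shorter/longer ≥ 0.95), cropped aspect ratio within 5% of the
configured card, and a red top-left center. Each translates to roughly an 18°
tilt limit, since the foreshortening of a tilted length goes as cos *t* and
arccos 0.95 = 18.19°. Then each spot's central window (25% of the spot size)
is averaged: mean gray below 128 means marked. Zero marks in a category give
`MISSING`, two or more give `AMBIGUOUS`; hard validation failures put an error
code in that image's CSV row and the batch moves on.

**Measurement.** Because the crop spans the corner-dot rectangle of known
millimetre size, mm-per-pixel is just `card_width_mm / crop_width_px`. The
flower is segmented by Otsu's threshold inside a circular region of interest
at the configured centroid, hole-filled, and measured: area = pixel count ×
(mm/px)², perimeter via a smoothed traced contour.

No real photographs are needed anywhere: `spotmark.synthetic_fixtures`
renders ground-truth card photographs (marks, rotation, projective tilt,
scale, noise, distractors, EXIF tags, synthetic flowers) for all testing.

## Worked example

```sh
spotmark create --category "Variety=A,B,C,D" --category "Plant=0-99" \
                --flower-mm 20 --out card
# wrote card.tif (98.0 x 84.0 mm, 24 spots) and card.spotcard.cfg

spotmark fixtures --preset failure_modes --out shots --seed 0   # or real photos
spotmark analyse --config card.spotcard.cfg --images shots --out results.csv \
                 --measure-flower --save-crops crops
# 3 images -> results.csv (2 ok, 1 errors)
```

A results CSV looks like:

```
filename,datetime,latitude,longitude,altitude,Variety,Plant,area_mm2,perimeter_mm,error
img0.jpg,2023-06-01T10:30:00,52.205,0.125,12,B,37,171.941,179.173,
img1.jpg,2023-06-01T10:30:00,52.205,0.125,12,C,5,202.22,50.666,
img2.jpg,2023-06-01T10:30:00,52.205,0.125,12,,,,,CORNERS_NOT_FOUND
```

One row per photograph, in filename order: capture time and GPS decoded from
EXIF (blank when absent), one column per category (`B`, `37`, … or `MISSING`/
`AMBIGUOUS`), flower area (mm²) and perimeter (mm) when requested, and a
machine-readable error code when a card failed validation — a failed image
never stops the batch.

The same operations are available as a library:

```python
from spotmark import layout_card, analyse_image, parse_category_input

layout = layout_card([parse_category_input("Variety", "A,B,C,D")])
detected, reading = analyse_image(photo_array, layout)
reading.values            # {'Variety': 'B'}
detected.mm_per_px        # physical scale of the crop
```

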