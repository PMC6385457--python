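# Methods

This note records the geometric model behind card reading, the constants that
matter and why they have the values they do, what the synthetic photographs do
and do not emulate, and the numerical choices made where the design was open.

## Card geometry and the configuration file

All card coordinates live in a template frame whose origin is the **top-left
corner-dot center**, x rightwards, y downwards. `card_width_mm` /
`card_height_mm` are the physical dimensions of the corner-dot-center
rectangle — not the paper edge — because detection crops to the dot centers,
which makes the scale computation exact: `mm_per_px = card_width_mm /
crop_width_px`. The raster size is quantised to whole pixels first and the
millimetre size derived back from it, so the pixel and physical aspect ratios
agree identically (the aspect validation depends on this).

Layout constants (module constants in `card_generate`, all in mm): 6 mm spots
on an 8 mm pitch, 10 mm corner dots with a center disc of one third their
diameter, 9 mm inset from the dot-center rectangle to the spot area, 5 mm
category captions, 300 dpi default raster, 7 mm print margin beyond the dot
centers. These are our own documented defaults; the card's overall footprint
follows from them.

With a flower preset, a spot-free clearance circle (flower diameter + 6 mm)
sits in the upper center with all category groups stacked below it. Placing
the clearance at the top — rather than between groups — means the stem-slit
indicator line never crosses a spot group, and adding a category appends
below existing ones, so existing spots never move relative to the clearance.
The flower centroid X is always half the card width; the centroid Y is the
clearance center and is recorded in the configuration file.

The configuration file is a versioned `key=value` text dialect (one key per
line, lists comma-separated, floats written with full `repr` precision so the
round-trip is the identity). A `no flower` sentinel records a card without a
flower. Every invariant is re-checked on load.

## Detection model

The reader applies, in order:

1. **Contrast adjustment** — a linear stretch mapping the 0.5th/99.5th
   percentiles of luminance to 0/1, applied equally to all channels (hue
   preserved). This makes the later fixed thresholds meaningful across
   exposure variation, deterministically.
2. **Fiducial mask** — HSV box thresholds (blue: hue 0.52–0.78, S ≥ 0.40,
   V ≥ 0.18; pink: hue 0.82–0.99, S ≥ 0.25, V ≥ 0.35), chosen so the
   generator's palette colors pass under at least ±30% illumination scaling
   and JPEG compression. The **four largest** connected components are the
   corner dots; smaller same-colored clutter is ignored by construction.
   Fewer than four components is a hard `CORNERS_NOT_FOUND`.
3. **Orientation** — each dot's center disc is classified as the nearest of
   the four reference colors in CIE Lab (a perceptual distance; ties and
   duplicate classifications raise `CENTERS_UNRESOLVED`). On an upright card
   the red→black and green→white diagonal unit vectors sum to a vector
   pointing straight down; the rotation applied is the angle bringing the
   observed sum onto +y. This needs no configuration data and has no
   wrap-around ambiguity (the sum's magnitude is bounded away from zero for
   any rectangle).
4. **Rectification** — rigid rotation only (bilinear), no perspective
   correction, matching the tool's stated constraint that cards face the
   camera. The crop edge on each side is the **average** of its two dot
   centers: under pure rotation this equals their common coordinate, and
   under residual keystone from the pinhole projection it cancels the
   near/far-edge size difference to first order (cropping to the bounding box
   instead shifts the effective tilt limit about 2° early).
5. **Validation** — (a) opposing diagonal lengths within 5% of each other
   (shorter/longer ≥ 0.95); (b) cropped aspect ratio within 5% of the
   configured card's; (c) the central portion of the top-left dot is red,
   sampled at the tracked dot center (under tilt about a diagonal the TL dot
   can sit a few pixels outside the mean-edge crop corner). Under
   orthographic foreshortening a tilted length scales as cos *t*, so both 5%
   tolerances correspond to a tilt limit of about 18°: arccos 0.95 = 18.19°
   for the diagonal check and for aspect about the y axis, arccos(1/1.05) =
   17.75° about the x axis.
6. **Reading** — spot centers are mapped from template to crop by independent
   x and y linear scales (this exactly compensates uniform foreshortening of
   a mildly tilted card); the mean gray of the central 25%-of-spot-size
   window is compared with a fixed cutoff of 128 (CLI-overridable). A fixed
   cutoff was chosen over per-card Otsu for determinism on all-blank cards.
   Value labels are printed inside spots in light gray (150) specifically so
   an unmarked spot always reads far above the cutoff; ink is near-black, so
   the margin on both sides is large.

Decoding is soft: per explicit category (or per digit row), zero marked spots
give `MISSING` and more than one gives `AMBIGUOUS`, without failing the
image. Hard failures (`CORNERS_NOT_FOUND`, `CENTERS_UNRESOLVED`,
`DIAGONAL_MISMATCH`, `ASPECT_MISMATCH`, `ORIENTATION_CHECK_FAILED`) abort
only the current image; the batch driver always emits one CSV row per input.

## Measurement

Scale comes from the crop as above; x and y scales agree within the 5%
aspect tolerance and their geometric mean is used for areas. The flower is
segmented inside a circular region of interest centered on the configured
centroid, of diameter 1.5× the flower preset but never larger than the
clearance minus 2 mm (so printed card never leaks into the mask; an
all-backing region with under-0.05 luminance range raises the soft
`FLOWER_NOT_FOUND` instead of measuring clutter). Otsu's threshold inside the
region separates the flower from the matt-black backing; the component at (or
nearest) the centroid is kept and hole-filled.

Area is the exact pixel count × (mm/px)². Perimeter is the length of the
marching-squares boundary contour smoothed with a 5-vertex circular moving
average: the raw contour overshoots smooth shapes by ~5.5% (staircase), the
smoothed one is within +0.5% on discs of 35–240 px radius and −2% on
squares. Both bounds are verified against closed forms in the tests.

## EXIF and output

DateTimeOriginal (fallback DateTime) is reported as ISO-8601 local time — no
timezone is inferred because EXIF carries none reliably. GPS
degrees/minutes/seconds rationals are signed by the N/S / E/W reference tags;
altitude by its reference byte. Absent tags yield blank cells, never errors.
The CSV is RFC 4180, UTF-8, LF, one row per image in lexicographic filename
order; missing values are empty cells.

## What the synthetic photographs emulate

The fixture renderer composites the rendered card into a scene through a true
planar homography: tilt about the x, y or either diagonal axis through the
card center, viewed by a pinhole camera at 10 card-widths' distance (so
small-angle behavior matches the orthographic cos *t* reasoning, with ~1%
keystone at 18°; `camera_distance_factor=None` gives exact orthographic
projection for geometry oracles). Marks are near-black (gray 20) discs
covering 80% of the spot area, emulating dry-wipe marker. Optional additive
Gaussian noise, a multiplicative illumination ramp, textured backgrounds, a
blue distractor disc, a "leaf" occluding a corner dot, a specular white patch
over a spot, a disc/ellipse flower on the black backing, and injected EXIF
tags (JPEG) cover the documented failure modes. Every stochastic element is
seeded; identical spec + seed reproduces identical bytes.

Not emulated: lens distortion, defocus, shadows cast across the card, motion
blur, non-planar (bent) cards, and specular reflection from lamination over
large areas. Passing tests therefore demonstrate correctness of the geometry,
decoding and measurement logic under realistic projective pose, noise and
compression — not robustness to every field pathology; the error taxonomy is
designed so such pathologies surface as explicit per-image error codes rather
than silent misreads.

## Problem sizes used in tests

The randomized round-trip property uses 200 rendered photographs with one to
two categories, rotation uniform in [0°, 360°), tilt up to 15° about a random
axis, render scale 4–16 px/mm (0.5–2× a nominal 8 px/mm) and noise up to
σ = 5; the tilt-robustness sweep uses 1° steps over 0–30°. Corner dots stay
near or above the recommended 60 px diameter at these scales. These sizes
exercise every code path while keeping the default test run quick.

## Known limitations

- Rigid rotation plus crop only: cards photographed with strong perspective
  are rejected by the validation checks rather than corrected.
- One card per photograph.
- The mark threshold is global per run; severely under-exposed photographs
  should be handled by the contrast stretch but extremely low-contrast marks
  (faint pencil) may read as blank — by design they then appear as `MISSING`.
- Byte-compatibility with other tools' configuration files is a non-goal; the
  format here is self-describing and versioned.
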