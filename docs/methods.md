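# Methods

## Scope and model

`uavweed` studies whether nearest-neighbour (NN) downsampling of a
high-resolution UAV ortho-mosaic can stand in for real higher-altitude
flights in early-season weed mapping of row crops.  The pipeline has four
stages — scene simulation, resampling, quality assessment, object-based
classification and treatment mapping — each usable on its own.

### Camera geometry

Ground sample distance follows the thin-lens nadir rule
`GSD = altitude · pixel_pitch / focal_length`.  The pixel pitch is taken
along the sensor *width* and rounded to 0.1 µm; this single convention
reproduces all four published pixel sizes of the two reference cameras
(RGB at 60/100 m: 1.84/3.07 cm; TTC: 3.25/5.42 cm) from their printed
sensor specifications, which neither the unrounded width- nor height-based
pitch does.  The RGB camera's 14–42 mm zoom is fixed at its 14 mm wide end,
the only focal length consistent with those pixel sizes.  The 30 m mosaic
GSDs (1.07 cm RGB, 1.6 cm TTC) are treated as *inputs*: they are set by the
mosaicking software and do not follow the optics formula.  GSDs are
reported rounded to 2 decimal cm; internal arithmetic is unrounded.

### Synthetic fields

The generator emulates a naturally infested sunflower field at the four-
to six-leaf stage.  All structure is explicit geometry — row centerlines,
weed ellipses, frame and marker rectangles — so labels rasterise
consistently at any GSD.  The local frame is planar, x east, y down,
metres.

Key parameters (defaults in parentheses):

- field size (100 × 100 m ≈ 1 ha, mirroring the emulated fields);
- row orientation 0–180° (0°) and spacing (0.70 m, typical sunflower; the
  true spacing of the emulated fields is unstated, so this is a convention);
- plant band width (0.20 m) and along-row plant coverage (0.85, rendered
  as dashed plant segments with a 0.5 m period and deterministic per-row
  phase);
- weed cover target (10% of field area) and patch half-width (0.15 m);
  weed patches are ellipses elongated along the row direction, centred on
  inter-row strip centerlines — never on a row line — and kept clear of
  the crop band so that vegetation objects do not merge across classes at
  fine GSD;
- class spectra as 8-bit digital-number means (soil 161/122/87/120 for
  R/G/B/NIR, matching published visible-band mosaic means; crop
  60/110/50/180; weed 70/120/55/170 — deliberately close to crop, since
  early weeds are spectrally similar) with per-class Gaussian noise
  (sd 8 DN, a typical consumer-sensor level);
- 32 sampling frames of 1 m², eight per infestation category.  Category
  bands are defined on *percent cover*: category 0 exactly weed-free,
  1 ∈ (0, 7.5], 2 ∈ (7.5, 17.5], 3 > 17.5.  Per-frame targets are drawn
  from ≈5% (U[3.5, 6.5]), 10–15% (U[10, 15]) and ≈20% (U[18, 25]) so that
  frame covers scatter the way visually categorised field frames do.  The
  generator paints weed ellipses inside each frame's inter-row chords and
  iteratively rescales them until the measured cover (pixel-centre rule on
  the base raster, 1 cm GSD) lands in the band; an infeasible design
  raises a configuration error.  A frame-pixel-count definition of the
  categories was rejected as internally inconsistent with a 1 m² frame at
  1.07 cm GSD; the percent definition is authoritative here.
- ≥20 ground control markers (0.4 m white squares, a typical GCP panel
  size) on a jittered grid with ≥5 m pairwise separation, kept ≥0.6 m away
  from frames so markers never overprint frame content.

`generate_scene` consumes a single seeded stream in documented order (row
phase → marker jitter → frame placement → category shuffle → frame patch
design → background patches).  `render_image` derives its noise stream
from (scenario seed, GSD, band set) instead of sharing that stream, so the
same render call yields the same image regardless of call order.

What the generator does *not* emulate: radiometric physics (BRDF, shadows),
mosaicking seams and geometric distortion, species-level weed structure,
within-class spectral gradients.  Passing tests therefore demonstrate the
*internal* consistency and recovery behaviour of the method under its own
assumptions, not performance on real imagery; in particular the synthetic
vegetation/soil contrast makes segmentation essentially perfect, which real
mosaics will not match.

### Nearest-neighbour resampler

Output dimensions are `floor(input · factor)` with
`factor = source_gsd / target_gsd`.  Pixel (r, c) has centre
(r + 0.5, c + 0.5) in grid units; each output centre maps to source
coordinates by division by the factor and takes the DN of the nearest
source centre.  An exact tie (possible for even integer down-factors) is
broken toward the upper-left source pixel — the reference ENVI behaviour is
unspecified, so the tie-break is declared, not inferred.  For factor `1/k`
the result provably equals taking every k-th pixel starting at
`ceil(k/2) − 1`, which `striding_oracle` implements independently and the
tests compare bit-exactly.  No new digital numbers can be created, which is
the mechanism behind unchanged band histograms after resampling.

### Positional and spectral quality

The ASPRS 1990 horizontal test is encoded as: Class-1 allowable RMSE =
0.025 cm × map-scale denominator (anchored by the published 1:50 → 1.25 cm
case), Class k limit = k × Class-1 limit, X and Y evaluated separately and
never pooled, the worse axis decides, and fewer than 20 check points is a
hard error.  Check-point discrepancies are measured automatically: each
marker is located in both images as the binary centroid of saturated
pixels (DN ≥ 200) inside a window of the marker extent plus 10 px around
the surveyed position; an undetected marker is reported missing.  Manual
digitisation in the emulated workflow is replaced by this detector, so
measured RMSEs include centroid quantisation (a fraction of the coarse
pixel) — sub-pixel by construction, matching the sub-centimetre to
~1.2 cm RMSEs the emulated workflow reports at these GSDs.

### Three-step OBIA classification

1. **Vegetation index**: ExG on chromatic coordinates for RGB imagery,
   NDVI for R/NIR.  Zero-denominator pixels get index 0.  The index choice
   is this package's (the reference rule set is unpublished); they are the
   standard visible/NIR discriminators.
2. **Segmentation**: Otsu threshold on the index, 8-connected components,
   objects below 4 px discarded as specks.  Otsu misbehaves on an
   effectively unimodal histogram (it halves the noise), so a separation
   statistic — the distance between the two class means over their pooled
   sd — must exceed 4; otherwise a fixed fallback threshold (ExG 0.05 /
   NDVI 0.2) is used with a warning.  Genuine scenes sit at separation
   ≥ 6.5 across all tested GSDs; pure soil noise at ≈ 2.7.
3. **Crop rows and classification**: the row orientation maximises the
   variance of the vegetation projection profile.  The sweep is two-stage
   (coarse 1.0°, then 0.25° within ±1.5° of the optimum, ties toward the
   smaller angle) — a single-pass 0.25° sweep gives identical results ~7×
   slower.  Spacing comes from the first strong local maximum of the
   profile autocorrelation (parabolic sub-bin refinement); detection fails
   unless the peak reaches 0.2, exceeds twice the mean absolute
   autocorrelation in the searched lag band, *and* the comb score — the
   mean autocorrelation at multiples of the candidate spacing — reaches
   0.3.  Row fields score ≈ 0.9 on the comb; random blob vegetation ≤ 0.11.
   Line phase is the circular mean of the across-row coordinate, refined
   per row by windowed centroids.  Objects whose centroid lies within the
   row half-width — `max(1.5 · plant_width/2, 2 px)`, configurable; no
   buffer width is published — of a detected line are crop, all others
   weed; pixels inherit their object's class, border objects included.
   Maps with less than 0.2% vegetation skip row detection and return an
   all-soil map.

### Treatment maps and concordance

Frame weed cover is the weed-pixel share of pixels whose centres fall in
the frame.  A frame is marked *Treatment* when cover **strictly exceeds**
the threshold; the strict rule is what makes the 0% threshold mean "treat
on any presence" (an "at least" reading would treat every frame at 0%).
Seven thresholds, 0–15% in steps of 2.5, are assessed.  Concordance at a
threshold is the percentage of frames with equal decisions in the two
maps; per-category summaries aggregate over all thresholds and report the
2 × 2 decision quadrants.  When two maps of different extent are compared
at field level, cover is computed over a common-area mask.

## Numerical and design choices

- All rasters are 8-bit DN; clipping and rounding happen once, at render.
- Rasterisation uses the pixel-centre-in-shape rule everywhere (labels,
  frames, markers), making counts at different GSDs consistent to ±1 px
  per edge.
- Row rasterisation is chunked (~64 MB float32 blocks) so 1-ha scenes at
  1 cm GSD stay within ordinary memory.
- The orientation sweep deterministically subsamples the vegetation mask
  above 2 × 10⁶ pixels; all tested scenes sit below the cap at the sizes
  used.
- GeoTIFF I/O writes ModelPixelScale/ModelTiepoint tags plus a JSON
  sidecar (band names, metadata) via `tifffile`; round-trips are lossless.
- Reports serialise with sorted keys and rounded floats, so a fixed
  config + seed reproduces byte-identical JSON.

## Problem sizes in tests and acceptance runs

The default scenario is the full ~1 ha field; it is used where single runs
suffice (frame-design checks, the 60 m R/NIR concordance experiment, which
runs in ~25 s).  Repeated-run studies — row-parameter recovery over
10 seeds × 3 orientations × 3 GSDs — use a 24 × 24 m field with the same
row geometry, frame design and marker constraints (`compact_scenario`),
keeping the 90-run study at a few minutes.  Row-detection accuracy is
insensitive to field size in this range because the profile already spans
dozens of rows at 24 m.

## Known limitations

- Synthetic spectra are class-constant plus white noise; segmentation
  accuracy on real mosaics will be lower and Otsu's threshold less stable.
- Object-level crop/weed assignment misclassifies weeds that touch a crop
  row (they merge into the row object).  The generator keeps patches clear
  of rows, so this failure mode is only partially exercised.
- Frame covers measured on ~3 cm grids carry ±1–2 percentage points of
  grid-sampling noise; frames whose true cover sits within that distance
  of a threshold can flip decisions between two otherwise identical maps.
  This is intrinsic to the comparison, not a classification error.
- The ASPRS implementation covers the 1990 horizontal standard only (no
  vertical accuracy, no 2014 standard, no geodetic datums).
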