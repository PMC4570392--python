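# uavweed

Tools for asking a practical question in drone-based precision agriculture:
**can you skip the high-altitude flight?**  Early-season weed mapping in row
crops (e.g. sunflower) needs centimetre-scale UAV ortho-mosaics, but low
flights are slow to acquire and expensive to mosaic.  An alternative is to
fly once at 30 m and *degrade* that mosaic by nearest-neighbour (NN)
resampling to the pixel sizes a 60 m or 100 m flight would have produced.
`uavweed` simulates this workflow end to end on synthetic fields with known
ground truth and quantifies whether the resampled imagery supports the same
weed maps and spraying decisions as imagery acquired at altitude.

It is aimed at remote-sensing and agronomy researchers who want a tested,
seeded sandbox for resampling / OBIA experiments, and at tool builders who
need the individual pieces (GSD arithmetic, NN resampler, ASPRS test,
row detection, threshold maps) as a library.

## What is inside

- **`cameras`** — camera models and the optics rule `GSD = H · p / f`
  (altitude × pixel pitch / focal length), with presets for a 12 Mpx
  visible camera (`RGB`) and a 1.3 Mpx multispectral camera (`TTC`), and the
  `xfactor = yfactor = source_gsd / target_gsd` resampling factors.
- **`synthetic`** — a seeded generator of ortho-scenes: parallel crop rows
  (0.70 m spacing), elliptical weed patches confined to the inter-row
  strips, 32 ground-truth 1 m² sampling frames in four infestation
  categories (0%, ≈5%, ≈10–15%, ≥20% cover; eight frames each), and ≥20
  high-contrast control markers.  Scenes rasterise consistently at any GSD.
- **`resample`** — the NN resampler (pixel-centre mapping, DN-preserving)
  plus an independent striding oracle for integer factors.
- **`quality`** — the ASPRS 1990 horizontal accuracy test: per-axis RMSE of
  ≥20 check points against the Class-1 limit `0.025 cm × scale denominator`
  (1:50 → 1.25 cm); Class 2/3 are twice/three times that; the worse axis
  decides.  Also per-band mean/sd preservation statistics.
- **`obia`** — the three-step object-based classification: (1) vegetation /
  soil segmentation (ExG or NDVI index, Otsu threshold, 8-connected
  objects); (2) spectral discrimination of vegetation; (3) crop/weed
  assignment by each object's distance to the detected crop-row structure
  (orientation from the projection-profile variance, spacing from the
  profile autocorrelation).  Every plant off the row lines is weed.
- **`assessment`** — frame weed covers, Treatment/No-Treatment decisions at
  the seven thresholds 0–15% (step 2.5, strict `cover > threshold`), and
  concordance reports between two classified maps.
- **`pipeline` / `cli`** — an end-to-end `full-run` experiment and thin
  subcommands (`simulate`, `resample`, `quality`, `weedmap`, `assess`).

## Worked example

```bash
python examples/03_resample_quality.py
```

```
30 m image 2242x2242 px -> resampled 781x781 px at 3.07 cm/px
band statistics (30 m source vs resampled):
  R: mean 128.94 -> 128.86 (delta -0.08), sd 47.88 -> 47.90
  G: mean 119.69 -> 119.67 (delta -0.02), sd 13.85 -> 13.84
  B: mean 76.12 -> 76.09 (delta -0.03), sd 22.91 -> 22.91
ASPRS: 20 points, RMSE X 0.77 cm, Y 0.49 cm, limiting axis X
-> Class 1 at 1:50 (Class-1 limit 1.25 cm)
```

Band means move by well under 1 DN — NN resampling rearranges digital
numbers, it never averages them — and the 20 marker displacements are
sub-pixel, so the degraded image passes the ASPRS test in Class 1, the most
precise class.  `examples/05_treatment_concordance.py` continues to the
agronomic endpoint: the resampled 60 m weed map and the directly rendered
60 m weed map assign the same Treatment/No-Treatment decision to 30–32 of
the 32 frames at every weed threshold, with disagreements confined to
low-infestation frames whose cover sits next to a threshold.

The other examples cover the camera arithmetic (`01`), the synthetic scene
and its fixture files (`02`), and the OBIA weed map itself (`04`).  The
whole design — two fields, both sensors, 60 m and 100 m, seven resampled
images — runs with:

```bash
uavweed full-run --out runs/demo --seed 0
```

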