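"""Generate a synthetic sunflower field with known ground truth.

Builds a compact (24 x 24 m) field: parallel crop rows, weed patches
confined to the inter-row strips, 32 ground-truth sampling frames in four
infestation categories, and 20 control markers.  Writes the fixture bundle
(GeoTIFF image + labels, CSV tables) into ./scene_fixture.
"""

import numpy as np

from uavweed import compact_scenario, generate_scene, render_image, write_fixture

scenario = compact_scenario(seed=1)
truth = generate_scene(scenario)

weed_frac = np.mean(truth.label_raster == 2)
print(f"field: {scenario.field_size_m[0]:.0f} x {scenario.field_size_m[1]:.0f} m, "
      f"{len(truth.row_offsets_m)} crop rows at {truth.row_spacing_m} m spacing")
print(f"achieved weed cover {100 * weed_frac:.1f}% "
      f"(target {100 * scenario.weed_cover_target:.0f}%)")

print("frames per category (true weed cover %):")
for cat in range(4):
    covers = sorted(f.true_cover_pct for f in truth.frames if f.category == cat)
    print(f"  category {cat}: " + ", ".join(f"{c:.1f}" for c in covers))

image = render_image(truth, scenario, 1.07, "RGB")
paths = write_fixture(truth, image, "scene_fixture")
print("fixture written:", *[str(p) for p in paths.values()], sep="\n  ")

# Category 0 frames are exactly weed-free; categories 1-3 target roughly 5%,
# 10-15% and >= 20% cover, the bands used for ground-truthing weed maps.
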