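"""Camera optics -> ground sample distance, and the resampling factors.

The pixel size on the ground (GSD) is altitude * pixel_pitch / focal_length.
Prints the 60 m and 100 m pixel sizes of both on-board cameras and the
factors that take a 30 m mosaic to those resolutions.
"""

from uavweed import (
    CAMERA_PRESETS,
    FlightSpec,
    gsd,
    pixel_pitch,
    resample_spec,
)

MOSAIC_GSD_30M = {"RGB": 1.07, "TTC": 1.6}  # set by the mosaicking software

for name, camera in CAMERA_PRESETS.items():
    print(f"{name}: pixel pitch {pixel_pitch(camera)} um "
          f"(sensor {camera.sensor_width_mm} mm / {camera.image_width_px} px)")
    for altitude in (60, 100):
        target = gsd(FlightSpec(altitude, camera))
        spec = resample_spec(MOSAIC_GSD_30M[name], target)
        print(f"  {altitude:>3} m flight -> {target:.2f} cm/px; "
              f"resample factor from 30 m mosaic: {spec.xfactor:.4f}")

# The factors are < 1: each 30 m mosaic is *down*sampled, i.e. the emulated
# higher flight has coarser pixels and fewer of them.
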