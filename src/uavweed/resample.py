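"""Nearest-neighbour spatial degradation of ortho-images.

Each output pixel centre is mapped into source-pixel coordinates and receives
the digital number of the source pixel whose centre is nearest, so the output
is a rearrangement of original values: no new digital numbers are created.
Pixel (r, c) has its centre at (r + 0.5, c + 0.5) in grid units; an exact tie
is broken toward the upper-left source pixel.
"""

from __future__ import annotations

import numpy as np

from .cameras import ResampleSpec
from .image import OrthoImage

__all__ = ["nn_resample", "striding_oracle"]


def _nearest_indices(n_out: int, factor: float, n_src: int) -> np.ndarray:
    x = (np.arange(n_out, dtype=np.float64) + 0.5) / factor
    idx = np.ceil(x).astype(np.int64) - 1  # half-down tie-break (upper-left)
    return np.clip(idx, 0, n_src - 1)


def nn_resample(image: OrthoImage, spec: ResampleSpec) -> OrthoImage:
    """Resample an ortho-image to ``spec.target_gsd_cm`` by nearest neighbour.

    Output dimensions are ``floor(input_dim * factor)``; the geospatial
    origin is preserved and the output GSD is the target GSD.  Upsampling
    (factor > 1) is permitted but flagged in ``extras['upsampled']``.
    """
    if abs(image.gsd_cm - spec.source_gsd_cm) > 1e-6:
        raise ValueError(
            f"image GSD {image.gsd_cm} does not match spec source "
            f"{spec.source_gsd_cm}"
        )
    ny, nx = image.shape
    ny_out = int(ny * spec.yfactor)
    nx_out = int(nx * spec.xfactor)
    if ny_out < 1 or nx_out < 1:
        raise ValueError("resample factor too small: output raster is empty")
    rows = _nearest_indices(ny_out, spec.yfactor, ny)
    cols = _nearest_indices(nx_out, spec.xfactor, nx)
    bands = {name: arr[np.ix_(rows, cols)] for name, arr in image.bands.items()}
    extras = dict(image.extras)
    extras.update(
        {
            "method": "nearest",
            "source_gsd_cm": image.gsd_cm,
            "xfactor": spec.xfactor,
            "yfactor": spec.yfactor,
            "upsampled": bool(spec.xfactor > 1.0 or spec.yfactor > 1.0),
        }
    )
    return OrthoImage(bands, spec.target_gsd_cm, tuple(image.origin_xy), extras)


def striding_oracle(image: OrthoImage, step: int) -> OrthoImage:
    """Pick every ``step``-th pixel under the same centre convention.

    Independent reference for integer down-factors: ``nn_resample`` with
    factor ``1/step`` must reproduce this output bit-exactly.
    """
    if not isinstance(step, (int, np.integer)) or isinstance(step, bool):
        raise TypeError("step must be an integer")
    if step < 1:
        raise ValueError("step must be >= 1")
    ny, nx = image.shape
    if ny // step < 1 or nx // step < 1:
        raise ValueError("step exceeds image dimension: output raster is empty")
    start = -(-step // 2) - 1  # ceil(step/2) - 1
    bands = {
        name: arr[start::step, start::step][: ny // step, : nx // step].copy()
        for name, arr in image.bands.items()
    }
    extras = dict(image.extras)
    extras.update({"method": "stride", "step": int(step),
                   "source_gsd_cm": image.gsd_cm})
    return OrthoImage(bands, image.gsd_cm * step, tuple(image.origin_xy), extras)
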