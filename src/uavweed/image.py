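"""Georeferenced multi-band 8-bit raster container.

The local frame is planar: x increases to the right (east), y increases
downward with the raster rows, both in metres.  ``origin_xy`` is the world
position of the upper-left image corner; pixel (row r, col c) covers the
square ``[c*g, (c+1)*g) x [r*g, (r+1)*g)`` relative to the origin, where
``g`` is the ground sample distance in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OrthoImage", "BAND_SETS"]

#: Minimum band names per supported band set.
BAND_SETS = {"RGB": ("R", "G", "B"), "R-NIR": ("R", "NIR")}


@dataclass
class OrthoImage:
    """Multi-band raster of 8-bit digital numbers with a GSD and origin.

    Parameters
    ----------
    bands : dict of str -> (H, W) uint8 arrays
        Band name to digital-number grid; all bands share one shape.
    gsd_cm : float
        Ground sample distance in centimetres per pixel.
    origin_xy : (float, float)
        World coordinates (m) of the upper-left corner.
    extras : dict
        Free-form provenance metadata (resampling factors, flags, ...).
    """

    bands: dict[str, np.ndarray]
    gsd_cm: float
    origin_xy: tuple[float, float] = (0.0, 0.0)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("image needs at least one band")
        if not self.gsd_cm > 0:
            raise ValueError("gsd must be > 0")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError("all bands must share one shape")
        for name, arr in self.bands.items():
            if arr.dtype != np.uint8:
                raise ValueError(f"band {name!r} must be uint8 digital numbers")
            if arr.ndim != 2:
                raise ValueError(f"band {name!r} must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    @property
    def gsd_m(self) -> float:
        return self.gsd_cm / 100.0

    def pixel_center_world(self, row, col):
        """World (x, y) in metres of the centre of pixel (row, col)."""
        g = self.gsd_m
        return (
            self.origin_xy[0] + (np.asarray(col) + 0.5) * g,
            self.origin_xy[1] + (np.asarray(row) + 0.5) * g,
        )

    def copy(self) -> "OrthoImage":
        return OrthoImage(
            {k: v.copy() for k, v in self.bands.items()},
            self.gsd_cm,
            tuple(self.origin_xy),
            dict(self.extras),
        )
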