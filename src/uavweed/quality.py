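"""Positional-accuracy (ASPRS 1990) and spectral-preservation checks.

The horizontal accuracy test follows the 1990 ASPRS standard: per-axis RMSE
of at least 20 check points is compared against the allowable limit for the
map scale.  Class 1 is the most precise; the Class-2 and Class-3 limits are
two and three times the Class-1 limit.  The X and Y axes are evaluated
separately and the worse one determines the class.  The Class-1 limiting
RMSE is 0.025 cm per unit of scale denominator (1:50 -> 1.25 cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image import OrthoImage
from .synthetic import ControlPoint

__all__ = [
    "PointPair",
    "ASPRSReport",
    "InsufficientPointsError",
    "rmse",
    "class1_limit",
    "asprs_test",
    "band_stats",
    "compare_stats",
    "measure_pairs",
]

#: ASPRS 1990 Class-1 limiting horizontal RMSE, cm per unit scale denominator.
CLASS1_CM_PER_SCALE = 0.025

MIN_CHECK_POINTS = 20


class InsufficientPointsError(ValueError):
    """Fewer than the 20 check points the ASPRS test requires."""


@dataclass(frozen=True)
class PointPair:
    """One check point located in the reference and in the test image (m)."""

    id: int
    reference_xy: tuple[float, float]
    test_xy: tuple[float, float]

    def __post_init__(self) -> None:
        for xy in (self.reference_xy, self.test_xy):
            if not all(math.isfinite(v) for v in xy):
                raise ValueError("point coordinates must be finite")


@dataclass(frozen=True)
class ASPRSReport:
    n_points: int
    rmse_x_cm: float
    rmse_y_cm: float
    scale_denominator: int
    class1_limit_cm: float
    achieved_class: int | str  # 1, 2, 3 or "fail"
    limiting_axis: str  # "X" or "Y"

    def as_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "rmse_x_cm": round(self.rmse_x_cm, 4),
            "rmse_y_cm": round(self.rmse_y_cm, 4),
            "scale_denominator": self.scale_denominator,
            "class1_limit_cm": self.class1_limit_cm,
            "achieved_class": self.achieved_class,
            "limiting_axis": self.limiting_axis,
        }


def rmse(discrepancies) -> float:
    """Square root of the average of the squared discrepancies."""
    d = np.asarray(discrepancies, dtype=float)
    if d.size == 0:
        raise ValueError("rmse of an empty discrepancy list is undefined")
    return float(np.sqrt(np.mean(d * d)))


def class1_limit(scale_denominator: int) -> float:
    """Allowable Class-1 horizontal RMSE (cm) for a map scale 1:denominator."""
    if not scale_denominator > 0:
        raise ValueError("scale denominator must be > 0")
    return CLASS1_CM_PER_SCALE * scale_denominator


def asprs_test(pairs, scale_denominator: int = 50) -> ASPRSReport:
    """Classify positional quality from reference/test point pairs."""
    pairs = list(pairs)
    if len(pairs) < MIN_CHECK_POINTS:
        raise InsufficientPointsError(
            f"ASPRS test requires >= {MIN_CHECK_POINTS} points, got {len(pairs)}"
        )
    dx_cm = [(p.test_xy[0] - p.reference_xy[0]) * 100.0 for p in pairs]
    dy_cm = [(p.test_xy[1] - p.reference_xy[1]) * 100.0 for p in pairs]
    rx, ry = rmse(dx_cm), rmse(dy_cm)
    limit1 = class1_limit(scale_denominator)
    worst = max(rx, ry)
    achieved: int | str = "fail"
    for k in (1, 2, 3):
        if worst <= k * limit1 + 1e-12:
            achieved = k
            break
    return ASPRSReport(
        n_points=len(pairs),
        rmse_x_cm=rx,
        rmse_y_cm=ry,
        scale_denominator=scale_denominator,
        class1_limit_cm=limit1,
        achieved_class=achieved,
        limiting_axis="X" if rx >= ry else "Y",
    )


def band_stats(image: OrthoImage) -> dict[str, tuple[float, float]]:
    """Per-band (mean, standard deviation) of the digital numbers."""
    return {
        name: (float(arr.mean()), float(arr.std()))
        for name, arr in image.bands.items()
    }


def compare_stats(a: OrthoImage, b: OrthoImage) -> dict[str, dict[str, float]]:
    """Per-band mean/sd deltas between two images (reported to 2 decimals)."""
    if a.band_names != b.band_names:
        raise ValueError(f"band sets differ: {a.band_names} vs {b.band_names}")
    sa, sb = band_stats(a), band_stats(b)
    out = {}
    for name in a.band_names:
        out[name] = {
            "mean_a": round(sa[name][0], 2),
            "mean_b": round(sb[name][0], 2),
            "sd_a": round(sa[name][1], 2),
            "sd_b": round(sb[name][1], 2),
            "delta_mean": round(sb[name][0] - sa[name][0], 2),
            "delta_sd": round(sb[name][1] - sa[name][1], 2),
        }
    return out


def _detect_marker(image: OrthoImage, cp: ControlPoint, marker_size_m: float,
                   search_margin_px: int, threshold: int):
    g = image.gsd_m
    ny, nx = image.shape
    half_px = int(math.ceil(marker_size_m / 2.0 / g)) + search_margin_px
    ec = (cp.x - image.origin_xy[0]) / g - 0.5
    er = (cp.y - image.origin_xy[1]) / g - 0.5
    r0 = max(0, int(round(er)) - half_px)
    r1 = min(ny, int(round(er)) + half_px + 1)
    c0 = max(0, int(round(ec)) - half_px)
    c1 = min(nx, int(round(ec)) + half_px + 1)
    if r1 <= r0 or c1 <= c0:
        return None
    window = np.max(
        np.stack([arr[r0:r1, c0:c1] for arr in image.bands.values()]), axis=0
    )
    mask = window >= threshold
    if not mask.any():
        return None
    rr, cc = np.nonzero(mask)
    row = r0 + rr.mean()
    col = c0 + cc.mean()
    return (
        image.origin_xy[0] + (col + 0.5) * g,
        image.origin_xy[1] + (row + 0.5) * g,
    )


def measure_pairs(
    reference: OrthoImage,
    test: OrthoImage,
    control_points,
    marker_size_m: float = 0.4,
    search_margin_px: int = 10,
    threshold: int = 200,
) -> tuple[list[PointPair], list[int]]:
    """Locate each control marker in both images and pair the centroids.

    Markers are found as the binary centroid of saturated pixels inside a
    window around the surveyed position (window = marker extent plus
    ``search_margin_px``).  Returns the detected pairs and the ids of
    markers missing from either image.
    """
    pairs: list[PointPair] = []
    missing: list[int] = []
    for cp in control_points:
        ref_xy = _detect_marker(reference, cp, marker_size_m,
                                search_margin_px, threshold)
        test_xy = _detect_marker(test, cp, marker_size_m,
                                 search_margin_px, threshold)
        if ref_xy is None or test_xy is None:
            missing.append(cp.id)
            continue
        pairs.append(PointPair(cp.id, ref_xy, test_xy))
    return pairs, missing
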