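"""Frame-based weed cover, threshold treatment maps and concordance.

A site-specific weed management (SSWM) plan marks each 1 m^2 sampling frame
for herbicide *Treatment* when its weed cover strictly exceeds a threshold;
seven thresholds from 0% to 15% in steps of 2.5 are assessed.  The strict
">" rule makes the 0% threshold mean "treat on any weed presence".
Concordance between two classified maps is the percentage of frames whose
Treatment/No-Treatment decisions agree at each threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .obia import ClassifiedMap
from .synthetic import WEED, SamplingFrame, _frame_pixel_window

__all__ = [
    "TREATMENT",
    "NO_TREATMENT",
    "FrameCover",
    "TreatmentMap",
    "ConcordanceReport",
    "threshold_series",
    "frame_weed_cover",
    "treatment_decision",
    "treatment_map",
    "concordance",
    "field_weed_cover",
]

TREATMENT = "Treatment"
NO_TREATMENT = "No-Treatment"


@dataclass
class FrameCover:
    """Weed cover (percent) of one frame in one or two classified maps."""

    frame_id: int
    cover_a: float
    cover_b: float | None = None
    category: int | None = None


@dataclass
class TreatmentMap:
    """Per-frame Treatment/No-Treatment decisions at one threshold."""

    threshold: float
    decisions: dict[int, str]


@dataclass
class ConcordanceReport:
    """Per-threshold and per-category agreement between two maps."""

    thresholds: list[float]
    match_pct: list[float]  # per threshold, over all frames
    per_category: dict[int, float]  # per category, over frames x thresholds
    n_frames: int
    field_cover_pair: tuple[float, float] | None = None
    quadrant_counts: dict = dataclass_field(default_factory=dict)

    def match_at(self, threshold: float) -> float:
        for t, m in zip(self.thresholds, self.match_pct):
            if abs(t - threshold) < 1e-9:
                return m
        raise KeyError(f"threshold {threshold} not in report")


def threshold_series() -> list[float]:
    """The seven assessed weed thresholds: 0% to 15% in steps of 2.5."""
    return [0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0]


def frame_weed_cover(cmap: ClassifiedMap, frame: SamplingFrame) -> float:
    """Percent of a frame's area classified as weed.

    Pixels count toward the frame when their centre lies inside it.
    Raises if the frame lies outside the raster.
    """
    x = frame.x - cmap.origin_xy[0]
    y = frame.y - cmap.origin_xy[1]
    r0, r1, c0, c1 = _frame_pixel_window(x, y, frame.side, cmap.gsd_cm,
                                         cmap.classes.shape)
    window = cmap.classes[r0:r1, c0:c1]
    return 100.0 * np.count_nonzero(window == WEED) / window.size


def treatment_decision(cover_pct: float, threshold_pct: float) -> str:
    """Treatment iff cover strictly exceeds the threshold."""
    if not 0.0 <= cover_pct <= 100.0:
        raise ValueError("cover must lie in [0, 100]")
    if not 0.0 <= threshold_pct <= 100.0:
        raise ValueError("threshold must lie in [0, 100]")
    return TREATMENT if cover_pct > threshold_pct else NO_TREATMENT


def treatment_map(covers: dict[int, float], threshold_pct: float) -> TreatmentMap:
    return TreatmentMap(
        threshold_pct,
        {fid: treatment_decision(c, threshold_pct) for fid, c in covers.items()},
    )


def concordance(
    covers_a: dict[int, float],
    covers_b: dict[int, float],
    thresholds: list[float] | None = None,
    categories: dict[int, int] | None = None,
    field_cover_pair: tuple[float, float] | None = None,
) -> ConcordanceReport:
    """Treatment/No-Treatment agreement between two sets of frame covers.

    Symmetric in its two arguments.  ``categories`` (frame id -> infestation
    category) adds per-category agreement aggregated over all thresholds and
    the per-quadrant decision counts.
    """
    if set(covers_a) != set(covers_b):
        raise ValueError("frame ids differ between the two cover sets")
    ids = sorted(covers_a)
    thresholds = list(threshold_series() if thresholds is None else thresholds)
    match_pct = []
    agree = {}  # (frame, threshold) -> bool
    for t in thresholds:
        da = treatment_map(covers_a, t).decisions
        db = treatment_map(covers_b, t).decisions
        hits = [da[i] == db[i] for i in ids]
        match_pct.append(100.0 * sum(hits) / len(ids))
        for i, hit in zip(ids, hits):
            agree[(i, t)] = hit
    per_category: dict[int, float] = {}
    quadrants: dict = {}
    if categories is not None:
        for cat in sorted(set(categories.values())):
            members = [i for i in ids if categories.get(i) == cat]
            if not members:
                continue
            hits = [agree[(i, t)] for i in members for t in thresholds]
            per_category[cat] = 100.0 * sum(hits) / len(hits)
            for t in thresholds:
                da = treatment_map(covers_a, t).decisions
                db = treatment_map(covers_b, t).decisions
                key = (cat, t)
                cell = {"TT": 0, "TN": 0, "NT": 0, "NN": 0}
                for i in members:
                    code = ("T" if da[i] == TREATMENT else "N") + (
                        "T" if db[i] == TREATMENT else "N"
                    )
                    cell[code] += 1
                quadrants[key] = cell
    return ConcordanceReport(
        thresholds=thresholds,
        match_pct=match_pct,
        per_category=per_category,
        n_frames=len(ids),
        field_cover_pair=field_cover_pair,
        quadrant_counts=quadrants,
    )


def field_weed_cover(cmap: ClassifiedMap, mask: np.ndarray | None = None) -> float:
    """Percent of the map (or of a common-area mask) classified as weed."""
    if cmap.classes.size == 0:
        raise ValueError("empty classified map")
    if mask is None:
        return 100.0 * np.count_nonzero(cmap.classes == WEED) / cmap.classes.size
    if mask.shape != cmap.classes.shape:
        raise ValueError("mask shape must match the classified raster")
    denom = np.count_nonzero(mask)
    if denom == 0:
        raise ValueError("common-area mask is empty")
    return 100.0 * np.count_nonzero((cmap.classes == WEED) & mask) / denom
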