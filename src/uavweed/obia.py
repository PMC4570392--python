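"""Three-step object-based classification of crop, weed and bare soil.

Step 1 segments the image into vegetation and soil-background objects
(vegetation-index threshold + connected components); step 2 discriminates
vegetation spectrally (ExG for visible imagery, NDVI when a near-infrared
band is present, thresholded automatically by Otsu's method); step 3 assigns
each vegetation object to crop or weed from the position of its centroid
relative to the detected crop-row structure: every plant not located on a
crop line is classified as a weed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .image import OrthoImage
from .synthetic import CROP, SOIL, WEED, GroundTruth

__all__ = [
    "VegObject",
    "RowModel",
    "ClassifiedMap",
    "OBIAParams",
    "SegmentationResult",
    "RowDetectionError",
    "vegetation_index",
    "segment_vegetation",
    "detect_crop_rows",
    "classify",
    "run_obia",
    "row_coverage_fraction",
]

logger = logging.getLogger(__name__)

#: fixed fallback thresholds when the index histogram is degenerate
FALLBACK_THRESHOLDS = {"exg": 0.05, "ndvi": 0.2}


class RowDetectionError(RuntimeError):
    """No periodic crop-row structure found in the vegetation mask."""


@dataclass
class OBIAParams:
    """Tunable parameters of the three-step classification."""

    min_object_area_px: int = 4
    row_halfwidth_m: float | None = None  # None -> max(1.5*plant_width/2, 2 px)
    plant_width_m: float = 0.2
    coarse_step_deg: float = 1.0
    fine_step_deg: float = 0.25
    min_spacing_m: float = 0.3
    max_spacing_m: float = 3.0
    sweep_max_points: int = 2_000_000

    def resolve_halfwidth(self, gsd_cm: float) -> float:
        if self.row_halfwidth_m is not None:
            return self.row_halfwidth_m
        return max(1.5 * self.plant_width_m / 2.0, 2.0 * gsd_cm / 100.0)


@dataclass
class VegObject:
    """A connected vegetation object."""

    id: int
    area_px: int
    area_m2: float
    centroid_xy: tuple[float, float]  # world metres
    mean_index: float


@dataclass
class RowModel:
    """Detected crop-row structure: parallel lines u = offset_k."""

    orientation_deg: float
    spacing_m: float
    offsets_m: np.ndarray
    row_halfwidth_m: float

    def distance_to_nearest_row(self, x, y):
        c = math.cos(math.radians(self.orientation_deg))
        s = math.sin(math.radians(self.orientation_deg))
        u = np.asarray(x) * c - np.asarray(y) * s
        return np.min(np.abs(u[..., None] - self.offsets_m[None, :]), axis=-1)


@dataclass
class SegmentationResult:
    mask: np.ndarray  # bool vegetation mask (small objects removed)
    objects: list[VegObject]
    labels: np.ndarray  # int connected-component labels, 0 = background
    threshold: float
    index_kind: str


@dataclass
class ClassifiedMap:
    """OBIA output raster over {0 soil, 1 crop, 2 weed}."""

    classes: np.ndarray  # uint8
    gsd_cm: float
    origin_xy: tuple[float, float] = (0.0, 0.0)
    row_model: RowModel | None = None
    params: dict = dataclass_field(default_factory=dict)


def vegetation_index(image: OrthoImage) -> np.ndarray:
    """Per-pixel vegetation index: ExG for RGB, NDVI for R/NIR imagery.

    ExG is computed on chromatic coordinates, ``2g - r - b`` with
    ``r = R/(R+G+B)`` etc.; NDVI is ``(NIR - R)/(NIR + R)``.  Pixels whose
    denominator is zero get index 0 by convention.
    """
    names = set(image.band_names)
    if {"R", "G", "B"} <= names:
        r = image.bands["R"].astype(np.float32)
        g = image.bands["G"].astype(np.float32)
        b = image.bands["B"].astype(np.float32)
        total = r + g + b
        out = np.zeros_like(total)
        np.divide(2.0 * g - r - b, total, out=out, where=total > 0)
        return out
    if {"R", "NIR"} <= names:
        r = image.bands["R"].astype(np.float32)
        nir = image.bands["NIR"].astype(np.float32)
        total = nir + r
        out = np.zeros_like(total)
        np.divide(nir - r, total, out=out, where=total > 0)
        return out
    raise ValueError(f"band set {image.band_names} supports neither ExG nor NDVI")


def index_kind_for(image: OrthoImage) -> str:
    return "exg" if {"R", "G", "B"} <= set(image.band_names) else "ndvi"


def segment_vegetation(
    index: np.ndarray,
    gsd_cm: float,
    min_object_area_px: int = 4,
    index_kind: str = "exg",
    origin_xy: tuple[float, float] = (0.0, 0.0),
) -> SegmentationResult:
    """Threshold the index (Otsu) and extract vegetation objects.

    Objects are 8-connected components of the thresholded mask with at least
    ``min_object_area_px`` pixels; smaller specks are returned to background.
    A degenerate (effectively single-valued) histogram falls back to a fixed
    index threshold with a warning.
    """
    index = np.asarray(index)
    if not np.isfinite(index).all():
        raise ValueError("index raster must be finite")
    threshold = None
    if np.ptp(index) < 1e-6:
        threshold = FALLBACK_THRESHOLDS[index_kind]
        warnings.warn(
            "degenerate index histogram; using fixed "
            f"{index_kind.upper()} threshold {threshold}",
            stacklevel=2,
        )
    else:
        threshold = float(threshold_otsu(index))
        mask_try = index > threshold
        degenerate = not mask_try.any() or mask_try.all()
        if not degenerate:
            # Otsu on a unimodal histogram just splits the noise in half;
            # require the two classes to be well separated (d' style)
            lo_vals, hi_vals = index[~mask_try], index[mask_try]
            spread = math.sqrt(0.5 * (lo_vals.var() + hi_vals.var()))
            if spread > 0:
                degenerate = (hi_vals.mean() - lo_vals.mean()) / spread < 4.0
        if degenerate:
            threshold = FALLBACK_THRESHOLDS[index_kind]
            warnings.warn(
                "index histogram is effectively unimodal; using fixed "
                f"{index_kind.upper()} threshold {threshold}",
                stacklevel=2,
            )
    mask = index > threshold
    labels = cc_label(mask, connectivity=2)
    n = labels.max()
    objects: list[VegObject] = []
    if n:
        flat = labels.ravel()
        areas = np.bincount(flat, minlength=n + 1)
        small = np.flatnonzero(areas < min_object_area_px)
        small = small[small > 0]
        if small.size:
            drop = np.isin(labels, small)
            mask = mask & ~drop
            labels = labels * ~drop
        rows_idx, cols_idx = np.nonzero(labels)
        lab_vals = labels[rows_idx, cols_idx]
        areas = np.bincount(lab_vals, minlength=n + 1)
        sum_r = np.bincount(lab_vals, weights=rows_idx, minlength=n + 1)
        sum_c = np.bincount(lab_vals, weights=cols_idx, minlength=n + 1)
        sum_i = np.bincount(lab_vals, weights=index[rows_idx, cols_idx],
                            minlength=n + 1)
        g = gsd_cm / 100.0
        for obj_id in np.flatnonzero(areas[1:] > 0) + 1:
            a = int(areas[obj_id])
            cy = sum_r[obj_id] / a
            cx = sum_c[obj_id] / a
            objects.append(
                VegObject(
                    id=int(obj_id),
                    area_px=a,
                    area_m2=a * g * g,
                    centroid_xy=(
                        origin_xy[0] + (cx + 0.5) * g,
                        origin_xy[1] + (cy + 0.5) * g,
                    ),
                    mean_index=float(sum_i[obj_id] / a),
                )
            )
    return SegmentationResult(mask, objects, labels, float(threshold), index_kind)


# ---------------------------------------------------------------------------
# crop-row detection


def _projection_variance(x, y, theta_deg, bins_lo, bins_hi):
    c = math.cos(math.radians(theta_deg))
    s = math.sin(math.radians(theta_deg))
    u = x * np.float32(c) - y * np.float32(s)
    counts, _ = np.histogram(u, bins=int(bins_hi - bins_lo) + 1,
                             range=(bins_lo, bins_hi))
    return float(np.var(counts))


def detect_crop_rows(
    mask: np.ndarray, gsd_cm: float, params: OBIAParams | None = None
) -> RowModel:
    """Recover the crop-row orientation, spacing and line offsets.

    The orientation maximises the variance of the vegetation projection
    profile, swept over 0-180 deg (coarse pass, then refined at 0.25 deg
    resolution, ties broken toward the smaller angle).  Spacing comes from
    the first strong peak of the profile's autocorrelation; the line phase
    from the circular mean of the across-row coordinate, with per-row
    centroid refinement.
    """
    params = params or OBIAParams()
    rows_idx, cols_idx = np.nonzero(mask)
    if rows_idx.size == 0:
        raise RowDetectionError("vegetation mask is empty")
    x_all = cols_idx.astype(np.float32) + 0.5
    y_all = rows_idx.astype(np.float32) + 0.5
    if x_all.size > params.sweep_max_points:
        stride = int(np.ceil(x_all.size / params.sweep_max_points))
        x, y = x_all[::stride], y_all[::stride]
    else:
        x, y = x_all, y_all

    diag = math.hypot(mask.shape[0], mask.shape[1])
    lo, hi = -diag, diag

    coarse = np.arange(0.0, 180.0, params.coarse_step_deg)
    scores = [_projection_variance(x, y, t, lo, hi) for t in coarse]
    best = coarse[int(np.argmax(scores))]
    fine = best + np.arange(-1.5 * params.coarse_step_deg,
                            1.5 * params.coarse_step_deg + 1e-9,
                            params.fine_step_deg)
    fine = np.unique(np.round(np.mod(fine, 180.0), 6))
    fine_scores = [_projection_variance(x, y, t, lo, hi) for t in fine]
    theta = float(fine[int(np.argmax(fine_scores))])

    # full-resolution profile at the chosen orientation
    c = math.cos(math.radians(theta))
    s = math.sin(math.radians(theta))
    u = x_all * np.float32(c) - y_all * np.float32(s)
    umin, umax = float(u.min()), float(u.max())
    nbins = max(int(umax - umin) + 1, 4)
    profile, edges = np.histogram(u, bins=nbins, range=(umin, umax))
    d = profile.astype(np.float64) - profile.mean()
    ac = np.correlate(d, d, mode="full")[len(d) - 1:]
    if ac[0] <= 0:
        raise RowDetectionError("flat projection profile")
    rho = ac / ac[0]

    g = gsd_cm / 100.0
    lag_lo = max(2, int(round(params.min_spacing_m / g)))
    lag_hi = min(len(rho) - 1, int(round(params.max_spacing_m / g)), len(rho) // 2)
    if lag_hi <= lag_lo + 1:
        raise RowDetectionError("profile too short to estimate row spacing")
    seg = rho[lag_lo:lag_hi]
    baseline = float(np.mean(np.abs(seg)))
    # a periodic profile shows an interior local maximum at the row spacing;
    # blob-like vegetation only decays monotonically from lag zero
    interior = np.flatnonzero(
        (seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])
    ) + 1
    peak_val = float(seg[interior].max()) if interior.size else -np.inf
    if not interior.size or peak_val < 0.2 or peak_val < 2.0 * baseline:
        raise RowDetectionError(
            f"no periodic row structure (autocorrelation peak {peak_val:.3f}, "
            f"baseline {baseline:.3f})"
        )
    # smallest local maximum within 85% of the best peak -> fundamental lag
    strong = interior[seg[interior] >= 0.85 * peak_val]
    rel = int(strong[0])
    lag = lag_lo + rel
    # a true row pattern is a comb: the autocorrelation stays elevated at
    # every multiple of the spacing, which blob fields cannot mimic
    comb_vals = []
    for k in range(1, 5):
        h0, h1 = int((k - 0.15) * lag), int((k + 0.15) * lag) + 1
        if h1 >= len(rho):
            break
        comb_vals.append(float(rho[h0:h1].max()))
    comb_score = float(np.mean(comb_vals)) if comb_vals else peak_val
    if comb_score < 0.3:
        raise RowDetectionError(
            f"autocorrelation peak at lag {lag} not supported by its "
            f"harmonics (comb score {comb_score:.3f})"
        )
    if 0 < lag < len(rho) - 1:  # parabolic sub-bin refinement
        y0, y1, y2 = rho[lag - 1], rho[lag], rho[lag + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-12:
            lag = lag + 0.5 * (y0 - y2) / denom
    spacing_px = float(lag)

    # global phase from the circular mean of u mod spacing
    ang = 2.0 * np.pi * (u / spacing_px)
    z = complex(np.mean(np.cos(ang)), np.mean(np.sin(ang)))
    phase_px = (math.atan2(z.imag, z.real) / (2.0 * math.pi)) * spacing_px
    phase_px %= spacing_px

    k0 = math.ceil((umin - phase_px) / spacing_px - 0.25)
    k1 = math.floor((umax - phase_px) / spacing_px + 0.25)
    offsets_px = phase_px + spacing_px * np.arange(k0, k1 + 1, dtype=float)

    # per-row centroid refinement inside a +/-0.3*spacing window
    j = np.rint((u - phase_px) / spacing_px).astype(np.int64)
    resid = u - (phase_px + j * spacing_px)
    in_win = np.abs(resid) <= 0.3 * spacing_px
    jw = j[in_win] - k0
    valid = (jw >= 0) & (jw < len(offsets_px))
    jw, rw = jw[valid], resid[in_win][valid]
    if jw.size:
        counts = np.bincount(jw, minlength=len(offsets_px))
        sums = np.bincount(jw, weights=rw, minlength=len(offsets_px))
        enough = counts >= 30
        shift = np.zeros(len(offsets_px))
        shift[enough] = sums[enough] / counts[enough]
        offsets_px = offsets_px + np.clip(shift, -0.25 * spacing_px,
                                          0.25 * spacing_px)

    model = RowModel(
        orientation_deg=theta,
        spacing_m=spacing_px * g,
        offsets_m=offsets_px * g,
        row_halfwidth_m=params.resolve_halfwidth(gsd_cm),
    )
    logger.info(
        "rows: orientation %.2f deg, spacing %.3f m, %d lines",
        model.orientation_deg, model.spacing_m, len(model.offsets_m),
    )
    return model


def classify(
    seg: SegmentationResult,
    row_model: RowModel,
    gsd_cm: float,
    origin_xy: tuple[float, float] = (0.0, 0.0),
) -> ClassifiedMap:
    """Assign every vegetation object to crop or weed by row distance.

    An object whose centroid lies within ``row_halfwidth`` of the nearest
    detected row centerline is crop; any other plant is weed.  Pixels
    inherit their object's class; everything else is bare soil.
    """
    lut = np.zeros(int(seg.labels.max()) + 1, dtype=np.uint8)
    if seg.objects:
        xs = np.array([o.centroid_xy[0] for o in seg.objects])
        ys = np.array([o.centroid_xy[1] for o in seg.objects])
        dist = row_model.distance_to_nearest_row(xs, ys)
        for obj, dd in zip(seg.objects, dist):
            lut[obj.id] = CROP if dd <= row_model.row_halfwidth_m else WEED
    classes = lut[seg.labels]
    return ClassifiedMap(
        classes=classes,
        gsd_cm=gsd_cm,
        origin_xy=origin_xy,
        row_model=row_model,
        params={"row_halfwidth_m": row_model.row_halfwidth_m},
    )


def run_obia(image: OrthoImage, params: OBIAParams | None = None) -> ClassifiedMap:
    """Full three-step pipeline: index -> segmentation -> rows -> crop/weed."""
    params = params or OBIAParams()
    kind = index_kind_for(image)
    index = vegetation_index(image)
    seg = segment_vegetation(
        index,
        image.gsd_cm,
        min_object_area_px=params.min_object_area_px,
        index_kind=kind,
        origin_xy=tuple(image.origin_xy),
    )
    meta = {
        "index": kind,
        "threshold": seg.threshold,
        "min_object_area_px": params.min_object_area_px,
    }
    veg_fraction = sum(o.area_px for o in seg.objects) / seg.mask.size
    if not seg.objects or veg_fraction < 0.002:
        logger.info("no meaningful vegetation (%.4f%% of pixels): "
                    "returning all-soil map", 100 * veg_fraction)
        return ClassifiedMap(
            classes=np.zeros(image.shape, dtype=np.uint8),
            gsd_cm=image.gsd_cm,
            origin_xy=tuple(image.origin_xy),
            row_model=None,
            params=meta,
        )
    # row detection works in pixel units relative to the image origin
    row_model_px = detect_crop_rows(seg.mask, image.gsd_cm, params)
    g = image.gsd_m
    ox, oy = image.origin_xy
    c = math.cos(math.radians(row_model_px.orientation_deg))
    s = math.sin(math.radians(row_model_px.orientation_deg))
    row_model = RowModel(
        orientation_deg=row_model_px.orientation_deg,
        spacing_m=row_model_px.spacing_m,
        offsets_m=row_model_px.offsets_m + (ox * c - oy * s),
        row_halfwidth_m=row_model_px.row_halfwidth_m,
    )
    cmap = classify(seg, row_model, image.gsd_cm, tuple(image.origin_xy))
    meta.update(
        {
            "orientation_deg": round(row_model.orientation_deg, 3),
            "spacing_m": round(row_model.spacing_m, 4),
            "row_halfwidth_m": row_model.row_halfwidth_m,
        }
    )
    cmap.params = meta
    logger.info("OBIA parameters: %s", meta)
    return cmap


def row_coverage_fraction(
    truth: GroundTruth, row_model: RowModel, sample_step_m: float = 0.05
) -> float:
    """Fraction of true row-centerline points inside the detected row bands.

    Samples the ground-truth centerlines every ``sample_step_m`` within the
    field and checks whether each point falls within ``row_halfwidth`` of a
    detected row line.
    """
    w, h = truth.field_size_m
    c = math.cos(math.radians(truth.orientation_deg))
    s = math.sin(math.radians(truth.orientation_deg))
    pts_x, pts_y = [], []
    for off in truth.row_offsets_m:
        px, py = off * c, -off * s
        span = None
        # clip centerline to the field rectangle
        from .synthetic import _clip_line_to_rect

        span = _clip_line_to_rect(px, py, s, c, 0.0, 0.0, w, h)
        if span is None:
            continue
        t = np.arange(span[0], span[1], sample_step_m)
        pts_x.append(px + t * s)
        pts_y.append(py + t * c)
    if not pts_x:
        return 0.0
    x = np.concatenate(pts_x)
    y = np.concatenate(pts_y)
    dist = row_model.distance_to_nearest_row(x, y)
    return float(np.mean(dist <= row_model.row_halfwidth_m))
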