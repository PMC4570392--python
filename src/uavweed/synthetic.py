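"""Seeded generator of sunflower-field ortho-scenes with known ground truth.

The scene emulates the study system of UAV weed-mapping campaigns in early
sunflower: parallel crop rows on bare soil, patchy broadleaved weed
infestation confined to the inter-row strips, 1 m^2 ground-truth sampling
frames in four infestation categories, and high-contrast square ground
control markers.  Everything is generated from explicit geometry (row lines,
weed ellipses, frame and marker rectangles), so class labels can be
rasterised consistently at any ground sample distance.

Local frame: x east, y down (image row direction), metres, origin at the
field's upper-left corner.  Row orientation ``theta`` (degrees, 0-180) is the
angle of the row direction from the +y axis, so ``theta = 0`` gives vertical
rows; the across-row coordinate is ``u = x cos(theta) - y sin(theta)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .image import BAND_SETS, OrthoImage

__all__ = [
    "SOIL",
    "CROP",
    "WEED",
    "FieldScenario",
    "SamplingFrame",
    "ControlPoint",
    "WeedPatch",
    "GroundTruth",
    "default_scenario",
    "compact_scenario",
    "generate_scene",
    "render_image",
    "write_fixture",
    "CATEGORY_BANDS",
]

SOIL, CROP, WEED = 0, 1, 2

#: Per-category admissible true-cover bands (percent, lower-exclusive,
#: upper-inclusive except category 3 which is open above).
CATEGORY_BANDS = {0: (0.0, 0.0), 1: (0.0, 7.5), 2: (7.5, 17.5), 3: (17.5, 100.0)}

# per-frame cover targets drawn uniformly from these ranges (percent):
# category 1 ~5%, category 2 ~10-15%, category 3 ~20%
_CATEGORY_TARGETS = {1: (3.5, 6.5), 2: (10.0, 15.0), 3: (18.0, 25.0)}

_DASH_PERIOD_M = 0.5  # sunflower plant spacing pattern along the row


class ScenarioConfigError(ValueError):
    """Raised when a scenario cannot support the required sampling design."""


def _default_spectra() -> dict:
    # 8-bit digital-number means; soil R/G/B matches the published band means
    # of the visible ortho-mosaics; weeds deliberately close to crop.
    return {
        "soil": {"R": 161.0, "G": 122.0, "B": 87.0, "NIR": 120.0},
        "crop": {"R": 60.0, "G": 110.0, "B": 50.0, "NIR": 180.0},
        "weed": {"R": 70.0, "G": 120.0, "B": 55.0, "NIR": 170.0},
    }


def _default_noise_sd() -> dict:
    return {"soil": 8.0, "crop": 8.0, "weed": 8.0}


@dataclass
class FieldScenario:
    """Parameters of a synthetic sunflower field.

    The defaults mirror the agronomy of the study system: ~1 ha field,
    0.70 m row spacing, 32 sampling frames (eight per infestation category),
    at least 20 ground control markers, ~10% field weed cover.
    """

    field_size_m: tuple[float, float] = (100.0, 100.0)
    row_orientation_deg: float = 0.0
    row_spacing_m: float = 0.7
    row_plant_width_m: float = 0.2
    crop_coverage_along_row: float = 0.85
    weed_patch_count: int | None = None
    weed_patch_radius_m: float = 0.15
    weed_cover_target: float = 0.10
    spectra: dict = dataclass_field(default_factory=_default_spectra)
    noise_sd: dict = dataclass_field(default_factory=_default_noise_sd)
    n_frames: int = 32
    n_control_points: int = 20
    control_min_separation_m: float = 5.0
    marker_size_m: float = 0.4
    base_gsd_cm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.row_spacing_m > self.row_plant_width_m > 0):
            raise ScenarioConfigError("need row_spacing > row_plant_width > 0")
        if not 0.0 <= self.row_orientation_deg < 180.0:
            raise ScenarioConfigError("row orientation must be in [0, 180)")
        for frac in (self.crop_coverage_along_row, self.weed_cover_target):
            if not 0.0 <= frac <= 1.0:
                raise ScenarioConfigError("fractions must lie in [0, 1]")
        for cls, bands in self.spectra.items():
            for band, mean in bands.items():
                if not 0.0 <= mean <= 255.0:
                    raise ScenarioConfigError(
                        f"spectral mean {cls}/{band}={mean} outside [0, 255]"
                    )
        if self.n_frames % 4 != 0:
            raise ScenarioConfigError("n_frames must be a multiple of 4")
        if self.n_control_points < 20:
            raise ScenarioConfigError("at least 20 control points are required")

    @property
    def frames_per_category(self) -> int:
        return self.n_frames // 4


@dataclass
class SamplingFrame:
    """A 1 x 1 m ground-truth frame; ``(x, y)`` is its upper-left corner."""

    id: int
    x: float
    y: float
    side: float
    category: int
    true_cover_pct: float


@dataclass
class ControlPoint:
    """Geo-located marker centre, rendered as a high-contrast square."""

    id: int
    x: float
    y: float


@dataclass
class WeedPatch:
    """Elliptical weed cluster, axes aligned with the crop rows.

    ``a`` is the half-axis along the row direction, ``b`` across it (m).
    """

    cx: float
    cy: float
    a: float
    b: float


@dataclass
class GroundTruth:
    """Full generating geometry plus the base-resolution label raster."""

    field_size_m: tuple[float, float]
    orientation_deg: float
    row_spacing_m: float
    row_offsets_m: np.ndarray  # across-row (u) positions of the centerlines
    row_plant_width_m: float
    crop_coverage_along_row: float
    dash_salt: int
    weed_patches: list[WeedPatch]
    frames: list[SamplingFrame]
    control_points: list[ControlPoint]
    marker_size_m: float
    base_gsd_cm: float
    label_raster: np.ndarray  # uint8 {0 soil, 1 crop, 2 weed} at base_gsd_cm

    def rasterize_labels(self, gsd_cm: float) -> np.ndarray:
        """Rasterise the scene geometry at an arbitrary GSD."""
        if abs(gsd_cm - self.base_gsd_cm) < 1e-12 and self.label_raster is not None:
            return self.label_raster
        labels = _rasterize_crop(self, gsd_cm)
        _paint_patches(labels, self.weed_patches, self, gsd_cm)
        return labels


# ---------------------------------------------------------------------------
# geometry helpers


def _trig(theta_deg: float) -> tuple[float, float]:
    t = math.radians(theta_deg)
    return math.cos(t), math.sin(t)


def _uv_of_points(x, y, theta_deg):
    c, s = _trig(theta_deg)
    return x * c - y * s, x * s + y * c


def _u_range(field_size, theta_deg):
    w, h = field_size
    c, s = _trig(theta_deg)
    us = [0.0, w * c, -h * s, w * c - h * s]
    return min(us), max(us)


def _dash_phase(k: np.ndarray, salt: int) -> np.ndarray:
    # deterministic, resolution-independent per-row phase in [0, period)
    v = np.sin(k * 12.9898 + salt * 0.7310 + 78.233) * 43758.5453
    return (v - np.floor(v)) * _DASH_PERIOD_M


def _raster_dims(field_size, gsd_cm) -> tuple[int, int]:
    g = gsd_cm / 100.0
    return int(field_size[1] / g), int(field_size[0] / g)  # (ny, nx)


def _rasterize_crop(truth: GroundTruth, gsd_cm: float) -> np.ndarray:
    """Label raster with crop rows only (chunked over rows for memory)."""
    g = gsd_cm / 100.0
    ny, nx = _raster_dims(truth.field_size_m, gsd_cm)
    c, s = _trig(truth.orientation_deg)
    sp = truth.row_spacing_m
    halfwidth = truth.row_plant_width_m / 2.0
    phase = float(truth.row_offsets_m[0]) if len(truth.row_offsets_m) else 0.0
    cover = truth.crop_coverage_along_row

    labels = np.zeros((ny, nx), dtype=np.uint8)
    xc = ((np.arange(nx, dtype=np.float32) + 0.5) * g).astype(np.float32)
    chunk = max(1, int(64e6 / max(nx, 1) / 4))  # ~64 MB of float32 per array
    for r0 in range(0, ny, chunk):
        r1 = min(ny, r0 + chunk)
        yc = ((np.arange(r0, r1, dtype=np.float32) + 0.5) * g)[:, None]
        u = xc[None, :] * np.float32(c) - yc * np.float32(s)
        w = np.mod(u - np.float32(phase), np.float32(sp))
        dist = np.minimum(w, np.float32(sp) - w)
        band = dist <= np.float32(halfwidth)
        if cover < 1.0:
            v = xc[None, :] * np.float32(s) + yc * np.float32(c)
            k = np.rint((u - np.float32(phase)) / np.float32(sp))
            dphase = _dash_phase(k, truth.dash_salt)
            on = np.mod(v - dphase, np.float32(_DASH_PERIOD_M)) < np.float32(
                cover * _DASH_PERIOD_M
            )
            band &= on
        labels[r0:r1][band] = CROP
    return labels


def _patch_bbox(patch: WeedPatch, theta_deg: float):
    c, s = _trig(theta_deg)
    tx, ty = s, c  # row direction
    nx_, ny_ = c, -s  # across-row direction
    hx = math.hypot(patch.a * tx, patch.b * nx_)
    hy = math.hypot(patch.a * ty, patch.b * ny_)
    return hx, hy


def _paint_patches(labels, patches, truth: GroundTruth, gsd_cm: float,
                   erase: bool = False) -> None:
    """Paint (or erase) weed ellipses; weed never overwrites crop."""
    g = gsd_cm / 100.0
    ny, nx = labels.shape
    c, s = _trig(truth.orientation_deg)
    for p in patches:
        hx, hy = _patch_bbox(p, truth.orientation_deg)
        c0 = max(0, int((p.cx - hx) / g) - 1)
        c1 = min(nx, int((p.cx + hx) / g) + 2)
        r0 = max(0, int((p.cy - hy) / g) - 1)
        r1 = min(ny, int((p.cy + hy) / g) + 2)
        if c0 >= c1 or r0 >= r1:
            continue
        xs = (np.arange(c0, c1) + 0.5) * g - p.cx
        ys = ((np.arange(r0, r1) + 0.5) * g - p.cy)[:, None]
        along = xs[None, :] * s + ys * c
        across = xs[None, :] * c - ys * s
        inside = (along / p.a) ** 2 + (across / p.b) ** 2 <= 1.0
        sub = labels[r0:r1, c0:c1]
        if erase:
            sub[inside & (sub == WEED)] = SOIL
        else:
            sub[inside & (sub != CROP)] = WEED


def _frame_pixel_window(frame_x, frame_y, side, gsd_cm, shape):
    """Index window of pixels whose centres fall inside the frame."""
    g = gsd_cm / 100.0
    c0 = int(math.ceil(frame_x / g - 0.5))
    c1 = int(math.floor((frame_x + side) / g - 0.5 - 1e-9)) + 1
    r0 = int(math.ceil(frame_y / g - 0.5))
    r1 = int(math.floor((frame_y + side) / g - 0.5 - 1e-9)) + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, shape[0]), min(c1, shape[1])
    if r1 <= r0 or c1 <= c0:
        raise ValueError("frame lies outside the raster")
    return r0, r1, c0, c1


def _measure_frame_cover(labels, frame_x, frame_y, side, gsd_cm) -> float:
    r0, r1, c0, c1 = _frame_pixel_window(frame_x, frame_y, side, gsd_cm, labels.shape)
    window = labels[r0:r1, c0:c1]
    return 100.0 * np.count_nonzero(window == WEED) / window.size


def _clip_line_to_rect(px, py, dx, dy, x0, y0, x1, y1):
    """Liang-Barsky clip of the line (px,py)+t(dx,dy) to a rectangle.

    Returns (tmin, tmax) or None if the line misses the rectangle.
    """
    tmin, tmax = -math.inf, math.inf
    for p, d, lo, hi in ((px, dx, x0, x1), (py, dy, y0, y1)):
        if abs(d) < 1e-12:
            if not lo <= p <= hi:
                return None
            continue
        t0, t1 = (lo - p) / d, (hi - p) / d
        if t0 > t1:
            t0, t1 = t1, t0
        tmin, tmax = max(tmin, t0), min(tmax, t1)
    if tmin >= tmax:
        return None
    return tmin, tmax


# ---------------------------------------------------------------------------
# scene generation


def default_scenario(seed: int = 0, **overrides) -> FieldScenario:
    """The full-size (~1 ha) default scenario."""
    return FieldScenario(seed=seed, **overrides)


def compact_scenario(seed: int = 0, **overrides) -> FieldScenario:
    """A 24 x 24 m field with the same sampling design.

    Small enough for quick parameter-recovery studies while still holding
    32 disjoint frames and 20 control markers at >= 5 m separation.
    """
    overrides.setdefault("field_size_m", (24.0, 24.0))
    return FieldScenario(seed=seed, **overrides)


def _place_control_points(scenario: FieldScenario, rng) -> list[ControlPoint]:
    w, h = scenario.field_size_m
    n = scenario.n_control_points
    sep = scenario.control_min_separation_m
    jit = 0.1
    margin = 1.2
    inner_x, inner_y = w - 2 * margin, h - 2 * margin
    best = None
    for ncols in range(1, n + 1):
        nrows = math.ceil(n / ncols)
        sx = inner_x / (ncols - 1) if ncols > 1 else math.inf
        sy = inner_y / (nrows - 1) if nrows > 1 else math.inf
        if sx >= sep + 2 * jit and sy >= sep + 2 * jit:
            score = min(sx, sy)
            if best is None or score > best[0]:
                best = (score, ncols, nrows, sx, sy)
    if best is None:
        raise ScenarioConfigError(
            f"field too small for {n} control points at {sep} m separation"
        )
    _, ncols, nrows, sx, sy = best
    pts = []
    for i in range(n):
        r, c = divmod(i, ncols)
        x = margin + c * (sx if ncols > 1 else 0.0) + rng.uniform(-jit, jit)
        y = margin + r * (sy if nrows > 1 else 0.0) + rng.uniform(-jit, jit)
        pts.append(ControlPoint(i + 1, float(np.clip(x, 0.5, w - 0.5)),
                                float(np.clip(y, 0.5, h - 0.5))))
    return pts


def _place_frames(scenario: FieldScenario, control_points, rng):
    w, h = scenario.field_size_m
    margin, cell, side = 1.5, 3.0, 1.0
    ncx = int((w - 2 * margin) / cell)
    ncy = int((h - 2 * margin) / cell)
    if ncx * ncy < scenario.n_frames:
        raise ScenarioConfigError(
            f"field too small for {scenario.n_frames} disjoint sampling frames"
        )
    cells = [(i, j) for j in range(ncy) for i in range(ncx)]
    rng.shuffle(cells)
    cp_xy = np.array([[p.x, p.y] for p in control_points])
    placed = []
    for (i, j) in cells:
        if len(placed) == scenario.n_frames:
            break
        cx0 = margin + i * cell
        cy0 = margin + j * cell
        span = cell - side
        for _ in range(20):
            fx = cx0 + rng.uniform(0.15, span - 0.15)
            fy = cy0 + rng.uniform(0.15, span - 0.15)
            # keep markers clear of the frame (0.6 m buffer)
            near = np.any(
                (cp_xy[:, 0] > fx - 0.6) & (cp_xy[:, 0] < fx + side + 0.6)
                & (cp_xy[:, 1] > fy - 0.6) & (cp_xy[:, 1] < fy + side + 0.6)
            )
            if not near:
                placed.append((fx, fy))
                break
    if len(placed) < scenario.n_frames:
        raise ScenarioConfigError(
            "could not place all sampling frames clear of control markers"
        )
    return placed


def _frame_strips(truth: GroundTruth, fx, fy, side):
    """Inter-row strip chords crossing a frame: list of (uc, midpoint, length)."""
    sp = truth.row_spacing_m
    c, s = _trig(truth.orientation_deg)
    corners_u = [
        fx * c - fy * s,
        (fx + side) * c - fy * s,
        fx * c - (fy + side) * s,
        (fx + side) * c - (fy + side) * s,
    ]
    lo, hi = min(corners_u), max(corners_u)
    phase = float(truth.row_offsets_m[0]) if len(truth.row_offsets_m) else 0.0
    base = phase + sp / 2.0
    k0 = math.ceil((lo - base) / sp - 0.15)
    k1 = math.floor((hi - base) / sp + 0.15)
    out = []
    for k in range(k0, k1 + 1):
        uc = base + k * sp
        px, py = uc * c, -uc * s  # a point with u == uc
        span = _clip_line_to_rect(px, py, s, c, fx, fy, fx + side, fy + side)
        if span is None:
            continue
        t0, t1 = span
        length = t1 - t0
        mid = (px + (t0 + t1) / 2 * s, py + (t0 + t1) / 2 * c)
        out.append((uc, mid, length))
    return out


def _design_frame_patches(truth, labels, frame_xy, category, target_pct, rng):
    """Paint weed ellipses inside a frame until its true cover lands in the
    category band; returns the patches."""
    fx, fy = frame_xy
    side = 1.0
    lo, hi = CATEGORY_BANDS[category]
    sp = truth.row_spacing_m
    b_max = sp / 2.0 - truth.row_plant_width_m / 2.0 - 0.06
    strips = [st for st in _frame_strips(truth, fx, fy, side) if st[2] >= 0.25]
    if not strips:
        strips = sorted(_frame_strips(truth, fx, fy, side), key=lambda s: -s[2])[:1]
    if not strips:  # cannot happen for spacing < frame extent
        raise ScenarioConfigError("no inter-row strip crosses a sampling frame")
    total_len = sum(st[2] for st in strips)
    area = target_pct / 100.0 * side * side
    patches = []
    for iteration in range(8):
        if patches:
            _paint_patches(labels, patches, truth, truth.base_gsd_cm, erase=True)
            patches = []
        for uc, mid, length in strips:
            b = min(b_max, 0.20)
            a = min((area * length / total_len) / (math.pi * b), 0.45 * length)
            if a < 0.02:
                continue
            patches.append(WeedPatch(mid[0], mid[1], a, b))
        _paint_patches(labels, patches, truth, truth.base_gsd_cm)
        achieved = _measure_frame_cover(labels, fx, fy, side, truth.base_gsd_cm)
        if achieved > lo and (achieved <= hi or category == 3):
            return patches, achieved
        scale = target_pct / max(achieved, 0.2)
        area *= min(max(scale, 0.5), 3.0)
    raise ScenarioConfigError(
        f"could not reach category-{category} cover band in a frame "
        f"(last achieved {achieved:.2f}%)"
    )


def _nearest_strip_center(u, phase, spacing):
    k = round((u - phase) / spacing - 0.5)
    return phase + k * spacing + spacing / 2.0


def _place_background_patches(truth, labels, scenario, frames, rng):
    """Scatter inter-row weed clusters until the field cover target is met."""
    w, h = scenario.field_size_m
    target = scenario.weed_cover_target
    total_px = labels.size
    c, s = _trig(truth.orientation_deg)
    phase = float(truth.row_offsets_m[0]) if len(truth.row_offsets_m) else 0.0
    sp = truth.row_spacing_m
    b_max = sp / 2.0 - truth.row_plant_width_m / 2.0 - 0.06
    b = min(scenario.weed_patch_radius_m, b_max)
    g = truth.base_gsd_cm / 100.0
    mean_area_px = math.pi * b * (3.0 * b) / (g * g)
    frame_rects = np.array([[f[0], f[1]] for f in frames]) if frames else np.empty((0, 2))
    cp_xy = np.array([[p.x, p.y] for p in truth.control_points])

    def weed_px():
        return np.count_nonzero(labels == WEED)

    def place(count):
        placed, attempts = 0, 0
        while placed < count and attempts < count * 6 + 50:
            attempts += 1
            x = rng.uniform(0.8, w - 0.8)
            y = rng.uniform(0.8, h - 0.8)
            elong = rng.uniform(2.0, 4.0)
            u = x * c - y * s
            uc = _nearest_strip_center(u, phase, sp)
            x += (uc - u) * c
            y -= (uc - u) * s
            patch = WeedPatch(x, y, elong * b, b)
            hx, hy = _patch_bbox(patch, truth.orientation_deg)
            if x - hx < 0.3 or x + hx > w - 0.3 or y - hy < 0.3 or y + hy > h - 0.3:
                continue
            if len(frame_rects) and np.any(
                (frame_rects[:, 0] - 0.5 < x + hx)
                & (frame_rects[:, 0] + 1.5 > x - hx)
                & (frame_rects[:, 1] - 0.5 < y + hy)
                & (frame_rects[:, 1] + 1.5 > y - hy)
            ):
                continue
            if len(cp_xy) and np.any(
                (np.abs(cp_xy[:, 0] - x) < hx + 0.4)
                & (np.abs(cp_xy[:, 1] - y) < hy + 0.4)
            ):
                continue
            _paint_patches(labels, [patch], truth, truth.base_gsd_cm)
            truth.weed_patches.append(patch)
            placed += 1

    needed_px = target * total_px - weed_px()
    count = scenario.weed_patch_count
    if count is None:
        count = max(0, math.ceil(needed_px / mean_area_px))
    place(count)
    # top up against overlap losses until within the +/-20% relative band
    for _ in range(6):
        deficit_px = target * total_px - weed_px()
        if deficit_px <= 0.12 * target * total_px:
            break
        place(math.ceil(deficit_px / mean_area_px))


def generate_scene(scenario: FieldScenario) -> GroundTruth:
    """Generate the ground-truth geometry and base label raster for a field.

    Deterministic given ``scenario.seed``: a single random stream drives, in
    order, the row phase, control-marker jitter, frame placement, category
    assignment, per-frame cover targets and the background weed patches.
    """
    if scenario.weed_cover_target <= 0.0:
        raise ScenarioConfigError(
            "weed_cover_target = 0 cannot support the four-category frame design"
        )
    rng = np.random.default_rng(scenario.seed)
    w, h = scenario.field_size_m
    sp = scenario.row_spacing_m

    phase = float(rng.uniform(0.0, sp))
    umin, umax = _u_range(scenario.field_size_m, scenario.row_orientation_deg)
    k0 = math.ceil((umin - phase) / sp)
    k1 = math.floor((umax - phase) / sp)
    offsets = phase + sp * np.arange(k0, k1 + 1, dtype=float)

    control_points = _place_control_points(scenario, rng)
    truth = GroundTruth(
        field_size_m=scenario.field_size_m,
        orientation_deg=scenario.row_orientation_deg,
        row_spacing_m=sp,
        row_offsets_m=offsets,
        row_plant_width_m=scenario.row_plant_width_m,
        crop_coverage_along_row=scenario.crop_coverage_along_row,
        dash_salt=scenario.seed,
        weed_patches=[],
        frames=[],
        control_points=control_points,
        marker_size_m=scenario.marker_size_m,
        base_gsd_cm=scenario.base_gsd_cm,
        label_raster=None,
    )

    frame_sites = _place_frames(scenario, control_points, rng)
    categories = np.repeat(np.arange(4), scenario.frames_per_category)
    rng.shuffle(categories)

    labels = _rasterize_crop(truth, scenario.base_gsd_cm)
    truth.label_raster = labels

    for idx, ((fx, fy), cat) in enumerate(zip(frame_sites, categories)):
        cat = int(cat)
        if cat == 0:
            truth.frames.append(SamplingFrame(idx + 1, fx, fy, 1.0, 0, 0.0))
            continue
        target = float(rng.uniform(*_CATEGORY_TARGETS[cat]))
        patches, achieved = _design_frame_patches(
            truth, labels, (fx, fy), cat, target, rng
        )
        truth.weed_patches.extend(patches)
        truth.frames.append(SamplingFrame(idx + 1, fx, fy, 1.0, cat, achieved))

    _place_background_patches(truth, labels, scenario, frame_sites, rng)

    # final per-frame covers from the finished raster; verify the design
    for f in truth.frames:
        f.true_cover_pct = _measure_frame_cover(labels, f.x, f.y, f.side,
                                                scenario.base_gsd_cm)
        lo, hi = CATEGORY_BANDS[f.category]
        if f.category == 0:
            if f.true_cover_pct != 0.0:
                raise ScenarioConfigError(f"category-0 frame {f.id} contains weed")
        elif not (lo < f.true_cover_pct and (f.true_cover_pct <= hi or f.category == 3)):
            raise ScenarioConfigError(
                f"frame {f.id} cover {f.true_cover_pct:.2f}% outside its "
                f"category-{f.category} band"
            )
    return truth


# ---------------------------------------------------------------------------
# rendering


def _band_code(band_names: tuple[str, ...]) -> int:
    return int.from_bytes("/".join(band_names).encode(), "little") % (2**31)


def _normalize_band_set(band_set: str) -> tuple[str, ...]:
    key = band_set.upper().replace("_", "-")
    if key in ("RNIR", "R-NIR", "NIR"):
        key = "R-NIR"
    if key not in BAND_SETS:
        raise ValueError(f"unknown band set {band_set!r}; use 'RGB' or 'R-NIR'")
    return BAND_SETS[key]


def render_image(
    truth: GroundTruth,
    scenario: FieldScenario,
    gsd_cm: float,
    band_set: str = "RGB",
    include_markers: bool = True,
) -> OrthoImage:
    """Render an 8-bit ortho-image of the scene at the requested GSD.

    Per-pixel digital numbers are drawn from the class's per-band normal
    model, then clipped and quantised to 0-255.  The random substream is
    keyed on (scenario seed, GSD, band set), so identical calls produce
    identical images independent of call order.
    """
    bands = _normalize_band_set(band_set)
    labels = truth.rasterize_labels(gsd_cm)
    if min(labels.shape) < 50:
        raise ValueError("GSD too coarse for the field: need >= 50 x 50 pixels")
    seed_seq = np.random.SeedSequence(
        [int(scenario.seed), int(round(gsd_cm * 10000)), _band_code(bands)]
    )
    rng = np.random.default_rng(seed_seq)
    class_order = ("soil", "crop", "weed")
    out: dict[str, np.ndarray] = {}
    for band in bands:
        means = np.array(
            [scenario.spectra[c][band] for c in class_order], dtype=np.float32
        )
        sds = np.array(
            [scenario.noise_sd[c] for c in class_order], dtype=np.float32
        )
        dn = means[labels]
        if sds.max() > 0:
            dn = dn + sds[labels] * rng.standard_normal(labels.shape,
                                                        dtype=np.float32)
        out[band] = np.clip(np.rint(dn), 0, 255).astype(np.uint8)
    image = OrthoImage(out, gsd_cm, (0.0, 0.0),
                       {"band_set": "-".join(bands), "source": "rendered"})
    if include_markers:
        _paint_markers(image, truth)
    return image


def _paint_markers(image: OrthoImage, truth: GroundTruth) -> None:
    g = image.gsd_m
    ny, nx = image.shape
    half = truth.marker_size_m / 2.0
    for cp in truth.control_points:
        c0 = max(0, int(math.ceil((cp.x - half) / g - 0.5)))
        c1 = min(nx, int(math.floor((cp.x + half) / g - 0.5)) + 1)
        r0 = max(0, int(math.ceil((cp.y - half) / g - 0.5)))
        r1 = min(ny, int(math.floor((cp.y + half) / g - 0.5)) + 1)
        for arr in image.bands.values():
            arr[r0:r1, c0:c1] = 255


def write_fixture(truth: GroundTruth, image: OrthoImage, directory) -> dict:
    """Write an image + labels + frame/control tables bundle to a directory.

    Thin convenience over :mod:`uavweed.io`; returns the written paths.
    """
    from . import io as uio

    return uio.write_fixture(truth, image, directory)
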