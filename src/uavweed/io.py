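"""Raster and table I/O.

Rasters are written as 8-bit TIFFs carrying the GeoTIFF ModelPixelScale and
ModelTiepoint tags (planar local frame, metres) plus a JSON sidecar with the
band names, GSD and free-form metadata, so the DN grid round-trips exactly.
An RGB PNG writer with the same sidecar (plus an ESRI world file) is
provided for quick looks.  Tables (sampling frames, control points) are
plain CSV with fixed, validated schemas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image as PILImage

from .image import OrthoImage
from .synthetic import ControlPoint, GroundTruth, SamplingFrame

__all__ = [
    "write_ortho_tiff",
    "read_ortho_tiff",
    "write_ortho_png",
    "read_ortho_png",
    "write_labels_tiff",
    "read_labels_tiff",
    "frames_to_csv",
    "frames_from_csv",
    "control_points_to_csv",
    "control_points_from_csv",
    "write_fixture",
    "load_config",
    "write_report_json",
]

FRAME_COLUMNS = ["id", "x", "y", "side", "category", "true_cover"]
CONTROL_COLUMNS = ["id", "x", "y"]


class FormatError(ValueError):
    """Malformed raster or table input."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _geotags(gsd_m: float, origin_xy) -> list:
    # GeoTIFF ModelPixelScaleTag (33550) and ModelTiepointTag (33922)
    return [
        (33550, "d", 3, (gsd_m, gsd_m, 0.0)),
        (33922, "d", 6, (0.0, 0.0, 0.0, origin_xy[0], origin_xy[1], 0.0)),
    ]


def write_ortho_tiff(image: OrthoImage, path) -> Path:
    """Write a multi-band ortho-image as an 8-bit GeoTIFF + JSON sidecar."""
    path = Path(path)
    data = np.stack([image.bands[b] for b in image.band_names], axis=0)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        extratags=_geotags(image.gsd_m, image.origin_xy),
    )
    meta = {
        "bands": list(image.band_names),
        "gsd_cm": image.gsd_cm,
        "origin_xy": list(image.origin_xy),
        "extras": _jsonable(image.extras),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_ortho_tiff(path) -> OrthoImage:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such raster: {path}")
    data = tifffile.imread(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(meta["bands"]):
        raise FormatError(
            f"{path}: {data.shape[0]} planes but {len(meta['bands'])} bands "
            "in sidecar"
        )
    bands = {name: np.ascontiguousarray(plane.astype(np.uint8))
             for name, plane in zip(meta["bands"], data)}
    return OrthoImage(bands, float(meta["gsd_cm"]),
                      tuple(meta["origin_xy"]), dict(meta.get("extras", {})))


def write_ortho_png(image: OrthoImage, path) -> Path:
    """RGB PNG + JSON sidecar + ESRI world file (.pgw)."""
    path = Path(path)
    if set(("R", "G", "B")) - set(image.band_names):
        raise FormatError("PNG export needs R, G and B bands")
    rgb = np.stack([image.bands[b] for b in ("R", "G", "B")], axis=-1)
    PILImage.fromarray(rgb, mode="RGB").save(path)
    meta = {
        "bands": ["R", "G", "B"],
        "gsd_cm": image.gsd_cm,
        "origin_xy": list(image.origin_xy),
        "extras": _jsonable(image.extras),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    g = image.gsd_m
    world = "\n".join(
        str(v)
        for v in (g, 0.0, 0.0, g,
                  image.origin_xy[0] + g / 2, image.origin_xy[1] + g / 2)
    )
    path.with_suffix(".pgw").write_text(world + "\n")
    return path


def read_ortho_png(path) -> OrthoImage:
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    rgb = np.asarray(PILImage.open(path).convert("RGB"))
    bands = {name: np.ascontiguousarray(rgb[..., i])
             for i, name in enumerate(("R", "G", "B"))}
    return OrthoImage(bands, float(meta["gsd_cm"]),
                      tuple(meta["origin_xy"]), dict(meta.get("extras", {})))


def write_labels_tiff(labels: np.ndarray, gsd_cm: float, path,
                      origin_xy=(0.0, 0.0)) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path,
        np.asarray(labels, dtype=np.uint8),
        photometric="minisblack",
        extratags=_geotags(gsd_cm / 100.0, origin_xy),
    )
    meta = {"gsd_cm": gsd_cm, "origin_xy": list(origin_xy),
            "palette": {"0": "soil", "1": "crop", "2": "weed"}}
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_labels_tiff(path) -> tuple[np.ndarray, float]:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.uint8)
    meta = json.loads(_sidecar(path).read_text())
    return labels, float(meta["gsd_cm"])


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def frames_to_csv(frames: list[SamplingFrame], path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "id": f.id,
                "x": f.x,
                "y": f.y,
                "side": f.side,
                "category": f.category,
                "true_cover": f.true_cover_pct,
            }
            for f in frames
        ],
        columns=FRAME_COLUMNS,
    ).to_csv(path, index=False)
    return path


def frames_from_csv(path) -> list[SamplingFrame]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, FRAME_COLUMNS, path)
    return [
        SamplingFrame(int(r.id), float(r.x), float(r.y), float(r.side),
                      int(r.category), float(r.true_cover))
        for r in df.itertuples()
    ]


def control_points_to_csv(points: list[ControlPoint], path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"id": p.id, "x": p.x, "y": p.y} for p in points],
        columns=CONTROL_COLUMNS,
    ).to_csv(path, index=False)
    return path


def control_points_from_csv(path) -> list[ControlPoint]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, CONTROL_COLUMNS, path)
    return [ControlPoint(int(r.id), float(r.x), float(r.y))
            for r in df.itertuples()]


def write_fixture(truth: GroundTruth, image: OrthoImage, directory) -> dict:
    """Write image + labels + frames + control points into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": write_ortho_tiff(image, directory / "image.tif"),
        "labels": write_labels_tiff(
            truth.rasterize_labels(image.gsd_cm), image.gsd_cm,
            directory / "labels.tif"
        ),
        "frames": frames_to_csv(truth.frames, directory / "frames.csv"),
        "control_points": control_points_to_csv(
            truth.control_points, directory / "control_points.csv"
        ),
    }
    return paths


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such config file: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def _jsonable(obj):
    """Recursively coerce numpy scalars/arrays so reports serialise cleanly."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 6)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report_json(report: dict, path) -> Path:
    """Deterministic JSON report: sorted keys, floats rounded to 6 decimals."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
    return path
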