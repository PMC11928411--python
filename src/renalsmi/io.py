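"""Readers and writers for every artifact the pipeline exchanges.

Formats are deliberately plain: cine loops as multi-page TIFF with a YAML
metadata sidecar (frame_rate, pixel_size); ROIs as GeoJSON polygons in
pixel coordinates or as a PNG label image (0 = background, 1 =
interlobular, 2 = interlobar; combined = union); all time series and tables
as UTF-8 comma-separated CSV with a header row and '.' decimal. Floats are
written with shortest-repr precision so read(write(x)) == x bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from matplotlib.path import Path as MplPath

from .ceus import TimeIntensityCurve
from .errors import FormatError, ValidationError
from .hemodynamics import VelocityTrace
from .smi import AreaRatioSeries, CineLoop, RoiSet

LABEL_VALUES = {"interlobular": 1, "interlobar": 2}


# ---------------------------------------------------------------------------
# cine loops


def write_cine(path, cine: CineLoop) -> Path:
    """Multi-page TIFF plus a ``<stem>.yaml`` metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, cine.frames, photometric="rgb")
    meta = {"frame_rate": float(cine.frame_rate)}
    if cine.pixel_size is not None:
        meta["pixel_size_mm"] = float(cine.pixel_size)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta), encoding="utf-8")
    return path


def read_cine(path) -> CineLoop:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cine file not found: {path}")
    sidecar = path.with_suffix(".yaml")
    if not sidecar.exists():
        raise FormatError(f"metadata sidecar not found: {sidecar}")
    meta = yaml.safe_load(sidecar.read_text(encoding="utf-8")) or {}
    if "frame_rate" not in meta:
        raise FormatError(f"{sidecar}: missing 'frame_rate'")
    frames = tifffile.imread(path)
    if frames.ndim == 3:  # single page -> (H, W, 3)
        frames = frames[None]
    return CineLoop(
        frames=frames,
        frame_rate=float(meta["frame_rate"]),
        pixel_size=meta.get("pixel_size_mm"),
    )


# ---------------------------------------------------------------------------
# ROIs


def write_roi_geojson(path, polygons: dict[str, np.ndarray]) -> Path:
    """Polygons as GeoJSON in pixel coordinates, x = column, y = row."""
    features = []
    for label, verts in polygons.items():
        verts = np.asarray(verts, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise FormatError(f"ROI '{label}': polygon must be (N, 2) xy")
        ring = verts.tolist()
        if ring[0] != ring[-1]:
            ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "properties": {"label": label},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1),
        encoding="utf-8",
    )
    return path


def read_roi_geojson(path) -> dict[str, np.ndarray]:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid GeoJSON ({exc})") from exc
    polygons: dict[str, np.ndarray] = {}
    for feat in doc.get("features", []):
        label = feat.get("properties", {}).get("label")
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon" or label is None:
            raise FormatError(
                f"{path}: every feature needs a 'label' property and Polygon "
                "geometry"
            )
        polygons[label] = np.asarray(geom["coordinates"][0], dtype=float)
    if not polygons:
        raise FormatError(f"{path}: no polygon features found")
    return polygons


def rasterize_polygons(
    polygons: dict[str, np.ndarray], shape: tuple[int, int]
) -> RoiSet:
    """Pixel-center inclusion rasterization (row-major, 0-based, origin
    top-left); pixel (r, c) has center (x, y) = (c, r). A ``combined`` mask
    is synthesized as the union when absent."""
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    centers = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    masks: dict[str, np.ndarray] = {}
    for label, verts in polygons.items():
        inside = MplPath(np.asarray(verts, dtype=float)).contains_points(
            centers, radius=1e-9
        )
        masks[label] = inside.reshape(h, w)
    if "combined" not in masks and masks:
        union = np.zeros(shape, dtype=bool)
        for m in masks.values():
            union |= m
        masks["combined"] = union
    return RoiSet(masks=masks, provenance="geojson")


def write_roi_labels(path, roi: RoiSet) -> Path:
    """PNG label image: 0 background, 1 interlobular, 2 interlobar."""
    img = np.zeros(roi.shape, dtype=np.uint8)
    for label, value in LABEL_VALUES.items():
        if label in roi.masks:
            img[roi.masks[label]] = value
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, img)
    return path


def read_roi_labels(path) -> RoiSet:
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:
        img = img[..., 0]
    masks: dict[str, np.ndarray] = {}
    for label, value in LABEL_VALUES.items():
        m = img == value
        if m.any():
            masks[label] = m
    if not masks:
        raise FormatError(f"{path}: no labeled ROI pixels (values 1/2) found")
    union = np.zeros(img.shape, dtype=bool)
    for m in masks.values():
        union |= m
    masks["combined"] = union
    return RoiSet(masks=masks, provenance="label_image")


# ---------------------------------------------------------------------------
# time series / tables (CSV dialect: UTF-8, comma, header row, '.' decimal)


def _write_csv_with_meta(path, df: pd.DataFrame, meta: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)
    return path


def _read_csv_with_meta(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k.strip()] = v
            else:
                fh.seek(pos)
                break
        try:
            df = pd.read_csv(fh, float_precision="round_trip")
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return df, meta


def write_series_csv(path, series: AreaRatioSeries) -> Path:
    return _write_csv_with_meta(
        path,
        pd.DataFrame({"t": series.t, "a": series.a}),
        {"roi_label": series.roi_label, "n_roi_pixels": series.n_roi_pixels},
    )


def read_series_csv(path) -> AreaRatioSeries:
    df, meta = _read_csv_with_meta(path)
    for col in ("t", "a"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    return AreaRatioSeries(
        t=df["t"].to_numpy(),
        a=df["a"].to_numpy(),
        roi_label=meta.get("roi_label", ""),
        n_roi_pixels=int(meta.get("n_roi_pixels", 0)),
    )


def write_tic_csv(path, tic: TimeIntensityCurve) -> Path:
    return _write_csv_with_meta(
        path,
        pd.DataFrame({"t": tic.t, "intensity_db": tic.intensity}),
        {"roi_label": tic.roi_label},
    )


def read_tic_csv(path) -> TimeIntensityCurve:
    df, meta = _read_csv_with_meta(path)
    cols = {c.lower(): c for c in df.columns}
    tcol = cols.get("t")
    icol = cols.get("intensity_db") or cols.get("intensity")
    if tcol is None or icol is None:
        raise FormatError(f"{path}: need columns t, intensity_db")
    return TimeIntensityCurve(
        t=df[tcol].to_numpy(),
        intensity=df[icol].to_numpy(),
        roi_label=meta.get("roi_label", ""),
    )


def write_trace_csv(path, trace: VelocityTrace) -> Path:
    return _write_csv_with_meta(
        path,
        pd.DataFrame({"t": trace.t, "v": trace.v}),
        {"vessel_kind": trace.vessel_kind},
    )


def read_trace_csv(path, vessel_kind: str | None = None) -> VelocityTrace:
    df, meta = _read_csv_with_meta(path)
    for col in ("t", "v"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    kind = vessel_kind or meta.get("vessel_kind", "artery")
    return VelocityTrace(
        t=df["t"].to_numpy(), v=df["v"].to_numpy(), vessel_kind=kind
    )


def write_cohort_csv(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_cohort_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cohort table not found: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if "group" not in df.columns:
        raise ValidationError(f"{path}: missing 'group' column")
    return df
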