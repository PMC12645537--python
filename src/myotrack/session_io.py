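"""Stack reading, two-file CSV export, overlay writing and session config.

Export follows a two-file convention: ``<base>_results.csv`` holds the
per-frame diameter and sensor measurements, ``<base>_table.csv`` the
timestamped event log (drug additions, automated pressure changes).
Files are RFC-4180 CSV, UTF-8, '.' decimal separator; absent quantities
are empty fields, never zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import (
    Calibration,
    FrameStack,
    MyotrackError,
    ParameterError,
    TrackLine,
    make_calibration,
)
from .edge_detection import DetectionParams
from .tracking import DiameterRecord, ResultTable, TrackParams

__all__ = [
    "InputError",
    "SessionConfig",
    "read_stack",
    "write_stack",
    "write_results_csv",
    "read_results_csv",
    "write_overlay",
    "load_config",
]

RESULTS_COLUMNS = [
    "time_s",
    "frame",
    "line_id",
    "outer_um",
    "inner_um",
    "wall_um",
    "status",
    "pressure_mmHg",
    "temperature_C",
]
TABLE_COLUMNS = ["time_s", "label", "value"]

# Rec. 601 luminance weights for RGB -> grayscale (ultrasound video exports)
_LUMA = np.array([0.299, 0.587, 0.114])


class InputError(MyotrackError):
    """Unreadable or inconsistent input file."""


def read_stack(
    path, frame_interval: float, calibration: Calibration
) -> FrameStack:
    """Read a multipage TIFF as a grayscale FrameStack.

    8/16-bit grayscale pages are used as-is; RGB pages are converted by
    Rec. 601 luminance (0.299 R + 0.587 G + 0.114 B).  All pages must
    share one size.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            shapes = {p.shape for p in tif.pages}
            if len(shapes) > 1:
                raise InputError(f"TIFF pages differ in size: {sorted(shapes)}")
            pages = tif.asarray()
    except (OSError, ValueError, tifffile.TiffFileError) as e:
        raise InputError(f"cannot read TIFF {path}: {e}") from e
    arr = np.asarray(pages)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].astype(np.float64) @ _LUMA
    elif arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] > 8:
        # single RGB page
        arr = (arr[..., :3].astype(np.float64) @ _LUMA)[None]
    elif arr.ndim != 3:
        raise InputError(f"unsupported TIFF layout with shape {arr.shape}")
    if arr.dtype == object:
        raise InputError("TIFF pages differ in size")
    return FrameStack(
        frames=arr.astype(np.float64),
        frame_interval=frame_interval,
        calibration=calibration,
        source_path=str(path),
    )


def write_stack(stack_or_frames, path) -> Path:
    """Write frames as a multipage TIFF (float data saved as 16-bit after
    clipping to [0, 65535]; already-integer data saved unchanged)."""
    path = Path(path)
    frames = (
        stack_or_frames.frames
        if isinstance(stack_or_frames, FrameStack)
        else np.asarray(stack_or_frames)
    )
    if np.issubdtype(frames.dtype, np.floating):
        frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), frames)
    return path


def _fmt(v: Optional[float]) -> str:
    return "" if v is None or (isinstance(v, float) and math.isnan(v)) else repr(float(v))


def write_results_csv(table: ResultTable, base_path) -> Tuple[Path, Path]:
    """Write the two-file CSV export; returns (results path, table path)."""
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    results_path = base.parent / (base.name + "_results.csv")
    table_path = base.parent / (base.name + "_table.csv")

    rows = []
    for r in table.records:
        rows.append(
            {
                "time_s": repr(float(r.time)),
                "frame": r.frame_index,
                "line_id": r.line_id,
                "outer_um": _fmt(r.outer_um),
                "inner_um": _fmt(r.inner_um),
                "wall_um": _fmt(r.wall_um),
                "status": r.status,
                "pressure_mmHg": _fmt(r.pressure_mmHg),
                "temperature_C": _fmt(r.temperature_C),
            }
        )
    df = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    df.to_csv(results_path, index=False, encoding="utf-8", lineterminator="\n")

    ev_rows = []
    for (t, label, pressure, temp) in table.events:
        value = pressure if pressure is not None else temp
        ev_rows.append(
            {"time_s": repr(float(t)), "label": label, "value": _fmt(value)}
        )
    pd.DataFrame(ev_rows, columns=TABLE_COLUMNS).to_csv(
        table_path, index=False, encoding="utf-8", lineterminator="\n"
    )
    return results_path, table_path


def read_results_csv(results_path) -> ResultTable:
    """Parse a ``*_results.csv`` back into a ResultTable (no events)."""
    df = pd.read_csv(results_path)
    table = ResultTable()
    for _, row in df.iterrows():
        def opt(col):
            v = row[col]
            return None if pd.isna(v) else float(v)

        table.add_record(
            DiameterRecord(
                frame_index=int(row["frame"]),
                time=float(row["time_s"]),
                line_id=int(row["line_id"]),
                outer_um=opt("outer_um"),
                inner_um=opt("inner_um"),
                wall_um=opt("wall_um"),
                status=str(row["status"]),
                pressure_mmHg=opt("pressure_mmHg"),
                temperature_C=opt("temperature_C"),
            )
        )
    return table


def _draw_line_px(img: np.ndarray, x0, y0, x1, y1, value) -> None:
    from skimage.draw import line as sk_line

    rr, cc = sk_line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
    h, w = img.shape
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    img[rr[ok], cc[ok]] = value


def _tick(img, line: TrackLine, pos_along: float, value, half=4) -> None:
    """Short tick perpendicular to the line at a position along it."""
    ux, uy = line.direction()
    if line.kind == "segment":
        x0, y0 = line.geometry[0], line.geometry[1]
    elif line.kind == "roi_horizontal":
        x, y, w, h = line.geometry
        x0, y0 = x, y + (h - 1) / 2.0
    else:
        x, y, w, h = line.geometry
        x0, y0 = x + (w - 1) / 2.0, y
    cx, cy = x0 + pos_along * ux, y0 + pos_along * uy
    nx, ny = -uy, ux
    _draw_line_px(img, cx - half * nx, cy - half * ny, cx + half * nx, cy + half * ny, value)


def write_overlay(
    stack: FrameStack,
    table: ResultTable,
    lines: Sequence[TrackLine],
    path,
) -> Path:
    """Write a copy of the stack with track lines and edge ticks drawn.

    Ticks sit at the outer (and inner, when present) edge positions,
    reconstructed symmetrically about each line's midpoint; outer and
    inner indicators use distinct gray levels.  Raw pixels elsewhere are
    untouched, and failed frames show the line but no ticks.
    """
    n = len(stack)
    by_frame = {}
    for r in table.records:
        by_frame.setdefault(r.frame_index, {})[r.line_id] = r
    if by_frame and max(by_frame) >= n:
        raise ParameterError("result table refers to frames beyond the stack")

    vmax = float(stack.frames.max()) if stack.frames.size else 255.0
    line_val = vmax
    outer_val = vmax
    inner_val = 0.75 * vmax
    out = stack.frames.copy()
    lines_by_id = {ln.id: ln for ln in lines}
    for fi in range(n):
        img = out[fi]
        for ln in lines:
            if ln.kind == "segment":
                x0, y0, x1, y1 = ln.geometry
            elif ln.kind == "roi_horizontal":
                x, y, w, h = ln.geometry
                x0, y0, x1, y1 = x, y + (h - 1) / 2.0, x + w - 1, y + (h - 1) / 2.0
            else:
                x, y, w, h = ln.geometry
                x0, y0, x1, y1 = x + (w - 1) / 2.0, y, x + (w - 1) / 2.0, y + h - 1
            _draw_line_px(img, x0, y0, x1, y1, line_val)
            rec = by_frame.get(fi, {}).get(ln.id)
            if rec is None or rec.outer_um is None:
                continue
            center = ln.length / 2.0
            scale = stack.calibration.scale
            half_od = rec.outer_um / scale / 2.0
            _tick(img, ln, center - half_od, outer_val)
            _tick(img, ln, center + half_od, outer_val)
            if rec.inner_um is not None:
                half_id = rec.inner_um / scale / 2.0
                _tick(img, ln, center - half_id, inner_val)
                _tick(img, ln, center + half_id, inner_val)
    return write_stack(out, path)


@dataclass
class SessionConfig:
    """A full offline-analysis session loaded from a YAML config."""

    calibration: Calibration
    lines: List[TrackLine] = field(default_factory=list)
    track_params: TrackParams = field(default_factory=TrackParams)
    frame_interval: float = 1.0
    protocol: Optional[dict] = None
    output_dir: str = "."
    seed: int = 0


def _calibration_from_cfg(cfg: dict) -> Calibration:
    cal = cfg.get("calibration", {})
    if "scale" in cal:
        return Calibration(scale=float(cal["scale"]), label=cal.get("label", ""))
    if "camera_pixel_um" in cal and "magnification" in cal:
        return make_calibration(
            float(cal["camera_pixel_um"]),
            float(cal["magnification"]),
            label=cal.get("label", ""),
        )
    raise ParameterError(
        "config must give calibration.scale or camera_pixel_um + magnification"
    )


def load_config(path) -> SessionConfig:
    """Load a YAML session config.

    Schema (all detection/tracking keys optional)::

        calibration: {scale: 0.5}            # or camera_pixel_um + magnification
        frame_interval: 0.5                  # seconds
        lines:
          - {id: 0, kind: roi_horizontal, geometry: [10, 10, 200, 60],
             n_scanlines: 10, mode: brightfield}
          - {id: 1, kind: segment, geometry: [30, 5, 30, 100], half_width: 2}
        detection: {smooth_window: 5, k: 3.0, band_prominence: 0.25,
                    min_separation: 5, invert: false}
        tracking: {mad_multiplier: 3.0, k_frames: 5, max_jump_fraction: 0.25}
        protocol: {start: 20, stop: 100, step: 20, hold: 120}
        seed: 0
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    cal = _calibration_from_cfg(cfg)
    lines = []
    for ld in cfg.get("lines", []):
        lines.append(
            TrackLine(
                id=int(ld["id"]),
                kind=str(ld["kind"]),
                geometry=tuple(ld["geometry"]),
                n_scanlines=int(ld.get("n_scanlines", 10)),
                half_width=float(ld.get("half_width", 2.0)),
                mode=str(ld.get("mode", "brightfield")),
            )
        )
    det = DetectionParams(**cfg.get("detection", {}))
    trk = TrackParams(detection=det, **cfg.get("tracking", {}))
    return SessionConfig(
        calibration=cal,
        lines=lines,
        track_params=trk,
        frame_interval=float(cfg.get("frame_interval", 1.0)),
        protocol=cfg.get("protocol"),
        output_dir=str(cfg.get("output_dir", ".")),
        seed=int(cfg.get("seed", 0)),
    )
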