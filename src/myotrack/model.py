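"""Core domain types for pressure-myography diameter tracking.

Coordinate convention used throughout the package: 0-based indices,
``x`` is the column and ``y`` the row, and positions refer to pixel
centres.  Sub-pixel positions are continuous coordinates in that frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Calibration",
    "TrackLine",
    "FrameStack",
    "MyotrackError",
    "CalibrationError",
    "DomainError",
    "ParameterError",
    "make_calibration",
    "px_to_um",
    "MAX_TRACK_LINES",
    "MIN_SEGMENT_LENGTH_PX",
]

MAX_TRACK_LINES = 5
MIN_SEGMENT_LENGTH_PX = 8.0

MODES = ("brightfield", "fluorescence", "ultrasound", "en_face")
LINE_KINDS = ("roi_horizontal", "roi_vertical", "segment")


class MyotrackError(Exception):
    """Base class for all errors raised by this package."""


class CalibrationError(MyotrackError):
    """Invalid calibration parameters."""


class DomainError(MyotrackError):
    """An argument lies outside the physically meaningful domain."""


class ParameterError(MyotrackError):
    """An algorithm parameter is inconsistent or out of range."""


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-micron scaling and its provenance.

    Parameters
    ----------
    scale:
        Microns per pixel in the image plane.
    camera_pixel_um:
        Physical pixel pitch of the camera sensor in microns, when known.
    magnification:
        Total optical magnification, when known.  When both provenance
        fields are present ``scale`` must equal their quotient.
    label:
        Free-text name so saved calibrations can be switched quickly
        (e.g. ``"10x brightfield"``).
    """

    scale: float
    camera_pixel_um: Optional[float] = None
    magnification: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.scale > 0) or not math.isfinite(self.scale):
            raise CalibrationError(f"scale must be positive, got {self.scale!r}")
        if self.camera_pixel_um is not None and self.magnification is not None:
            expected = self.camera_pixel_um / self.magnification
            if abs(self.scale - expected) > 1e-9:
                raise CalibrationError(
                    f"scale {self.scale} inconsistent with "
                    f"{self.camera_pixel_um}/{self.magnification} = {expected}"
                )


def make_calibration(
    camera_pixel_um: float, magnification: float, label: str = ""
) -> Calibration:
    """Build a calibration from camera pixel pitch and magnification.

    The image-plane sampling is ``camera_pixel_um / magnification`` µm per
    pixel; e.g. a 3.45 µm pixel camera behind a 4x objective samples at
    0.8625 µm/pixel.
    """
    if not (camera_pixel_um > 0):
        raise CalibrationError(
            f"camera_pixel_um must be positive, got {camera_pixel_um!r}"
        )
    if not (magnification > 0):
        raise CalibrationError(f"magnification must be positive, got {magnification!r}")
    return Calibration(
        scale=camera_pixel_um / magnification,
        camera_pixel_um=camera_pixel_um,
        magnification=magnification,
        label=label,
    )


def px_to_um(cal: Calibration, length_px: float) -> float:
    """Convert a pixel length to microns using the calibration scale."""
    if length_px < 0:
        raise DomainError(f"length_px must be non-negative, got {length_px!r}")
    return float(length_px) * cal.scale


@dataclass(frozen=True)
class TrackLine:
    """A measurement locus along which intensity profiles are sampled.

    Three kinds are supported: horizontal and vertical ROI boxes, whose
    scanlines run along the rows/columns of the rectangle, and free
    segments drawn at any angle, sampled on the segment itself and on
    parallel lines offset perpendicular to it by up to ``half_width``.

    ``geometry`` is ``(x, y, width, height)`` for ROI kinds and
    ``(x0, y0, x1, y1)`` for segments, in pixel coordinates.
    """

    id: int
    kind: str
    geometry: tuple
    n_scanlines: int = 10
    half_width: float = 2.0
    mode: str = "brightfield"

    def __post_init__(self) -> None:
        if self.kind not in LINE_KINDS:
            raise ParameterError(f"unknown line kind {self.kind!r}")
        if self.mode not in MODES:
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.n_scanlines < 1:
            raise ParameterError("n_scanlines must be >= 1")
        if self.half_width < 0:
            raise ParameterError("half_width must be >= 0")
        geom = tuple(float(g) for g in self.geometry)
        object.__setattr__(self, "geometry", geom)
        if len(geom) != 4:
            raise ParameterError("geometry must have 4 components")
        if self.kind == "segment":
            if self.length < MIN_SEGMENT_LENGTH_PX:
                raise ParameterError(
                    f"segment length {self.length:.2f} px is below the "
                    f"minimum of {MIN_SEGMENT_LENGTH_PX} px"
                )
        else:
            x, y, w, h = geom
            if w <= 0 or h <= 0:
                raise ParameterError("ROI width and height must be positive")

    @property
    def length(self) -> float:
        """Length in pixels of one scanline of this track line."""
        if self.kind == "segment":
            x0, y0, x1, y1 = self.geometry
            return math.hypot(x1 - x0, y1 - y0)
        x, y, w, h = self.geometry
        return (w - 1.0) if self.kind == "roi_horizontal" else (h - 1.0)

    def validate_in_frame(self, shape: tuple) -> None:
        """Raise ParameterError unless the geometry (including all scanline
        offsets) lies fully inside a frame of the given (rows, cols) shape."""
        h_img, w_img = shape[0], shape[1]
        if self.kind == "segment":
            x0, y0, x1, y1 = self.geometry
            ux, uy = self.direction()
            # perpendicular offsets sweep +-half_width
            px, py = -uy, ux
            for s in (-self.half_width, self.half_width):
                for x, y in ((x0 + s * px, y0 + s * py), (x1 + s * px, y1 + s * py)):
                    if not (0 <= x <= w_img - 1 and 0 <= y <= h_img - 1):
                        raise ParameterError(
                            f"line {self.id}: segment (with half_width sweep) "
                            f"exits the frame at ({x:.1f}, {y:.1f})"
                        )
        else:
            x, y, w, h = self.geometry
            if not (0 <= x and x + w - 1 <= w_img - 1 and 0 <= y and y + h - 1 <= h_img - 1):
                raise ParameterError(f"line {self.id}: ROI exits the frame")

    def direction(self) -> tuple:
        """Unit vector along the scanline direction."""
        if self.kind == "segment":
            x0, y0, x1, y1 = self.geometry
            L = math.hypot(x1 - x0, y1 - y0)
            return ((x1 - x0) / L, (y1 - y0) / L)
        return (1.0, 0.0) if self.kind == "roi_horizontal" else (0.0, 1.0)


@dataclass
class FrameStack:
    """An ordered stack of 2-D grayscale frames with timing and calibration."""

    frames: np.ndarray
    frame_interval: float
    calibration: Calibration
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, :, :]
        if self.frames.ndim != 3:
            raise ParameterError("frames must be a (n, rows, cols) array")
        if self.frames.shape[0] < 1:
            raise ParameterError("stack must contain at least one frame")
        if not (self.frame_interval > 0):
            raise ParameterError("frame_interval must be positive")

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple:
        return tuple(self.frames.shape[1:])

    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t = 0)."""
        return np.arange(len(self)) * self.frame_interval


def validate_lines(lines: Sequence[TrackLine], frame_shape: tuple) -> None:
    """Check a session's track lines: count limit, unique ids, in-frame."""
    if len(lines) == 0:
        raise ParameterError("at least one track line is required")
    if len(lines) > MAX_TRACK_LINES:
        raise ParameterError(
            f"at most {MAX_TRACK_LINES} track lines per session, got {len(lines)}"
        )
    ids = [ln.id for ln in lines]
    if len(set(ids)) != len(ids):
        raise ParameterError(f"track line ids must be unique, got {ids}")
    for ln in lines:
        ln.validate_in_frame(frame_shape)
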