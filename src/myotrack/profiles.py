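"""Intensity-profile primitives: sampling along track lines, smoothing,
differentiation and 1-D peak detection.

Edge detection downstream works on the spatial derivative dF/dx of an
intensity profile F sampled at unit (1-pixel) spacing, so everything here
keeps that spacing and reports positions in profile-sample coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import ndimage

from .model import ParameterError, TrackLine

__all__ = [
    "IntensityProfile",
    "extract_profile",
    "scanline_offsets",
    "smooth_profile",
    "differentiate",
    "detect_peaks",
]

MIN_PROFILE_LENGTH = 8


@dataclass(frozen=True)
class IntensityProfile:
    """Intensity samples F at unit spacing along a line in the image.

    ``origin`` is the continuous (x, y) position of sample 0 and
    ``direction`` the unit vector of increasing sample index, so sample i
    lies at ``origin + i * direction``.
    """

    values: np.ndarray
    origin: tuple
    direction: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < MIN_PROFILE_LENGTH:
            raise ParameterError(
                f"profile must be 1-D with >= {MIN_PROFILE_LENGTH} samples"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def position_xy(self, s: float) -> tuple:
        """Image (x, y) coordinates of continuous profile position ``s``."""
        ox, oy = self.origin
        dx, dy = self.direction
        return (ox + s * dx, oy + s * dy)


def scanline_offsets(line: TrackLine) -> List[float]:
    """Offsets of every scanline of a track line.

    ROI kinds return the ``n_scanlines`` evenly spaced row/column indices
    (relative, 0 .. height-1 or width-1); segments return integer
    perpendicular shifts in ``[-half_width, +half_width]``.
    """
    if line.kind == "segment":
        hw = int(np.floor(line.half_width))
        return [float(s) for s in range(-hw, hw + 1)]
    x, y, w, h = line.geometry
    extent = (h - 1.0) if line.kind == "roi_horizontal" else (w - 1.0)
    if line.n_scanlines == 1:
        return [extent / 2.0]
    return list(np.linspace(0.0, extent, line.n_scanlines))


def extract_profile(
    frame: np.ndarray, line: TrackLine, scan_offset: float = 0.0
) -> IntensityProfile:
    """Sample one scanline of a track line by bilinear interpolation.

    For ROI kinds ``scan_offset`` is the row (horizontal) or column
    (vertical) offset within the rectangle; for segments it shifts the
    segment perpendicular to itself.  Samples are taken at unit steps, so
    the profile has ``floor(line length) + 1`` samples.
    """
    frame = np.asarray(frame, dtype=np.float64)
    h_img, w_img = frame.shape
    if line.kind == "segment":
        x0, y0, x1, y1 = line.geometry
        ux, uy = line.direction()
        if not (-line.half_width <= scan_offset <= line.half_width):
            raise ParameterError(
                f"scan_offset {scan_offset} outside +-half_width {line.half_width}"
            )
        # perpendicular (left-hand) normal
        ox = x0 - uy * scan_offset
        oy = y0 + ux * scan_offset
        n = int(np.floor(line.length)) + 1
    elif line.kind == "roi_horizontal":
        x, y, w, h = line.geometry
        if not (0 <= scan_offset <= h - 1):
            raise ParameterError("scan_offset outside ROI height")
        ox, oy = x, y + scan_offset
        ux, uy = 1.0, 0.0
        n = int(np.floor(w - 1.0)) + 1
    else:  # roi_vertical
        x, y, w, h = line.geometry
        if not (0 <= scan_offset <= w - 1):
            raise ParameterError("scan_offset outside ROI width")
        ox, oy = x + scan_offset, y
        ux, uy = 0.0, 1.0
        n = int(np.floor(h - 1.0)) + 1

    s = np.arange(n, dtype=np.float64)
    xs = ox + s * ux
    ys = oy + s * uy
    eps = 1e-9
    if (
        xs.min() < -eps
        or xs.max() > w_img - 1 + eps
        or ys.min() < -eps
        or ys.max() > h_img - 1 + eps
    ):
        raise ParameterError(
            f"line {line.id}: scanline at offset {scan_offset} exits the frame"
        )
    # map_coordinates takes (row, col) order
    vals = ndimage.map_coordinates(
        frame, np.vstack([ys, xs]), order=1, mode="nearest"
    )
    return IntensityProfile(values=vals, origin=(ox, oy), direction=(ux, uy))


def smooth_profile(p: IntensityProfile, window: int = 5) -> IntensityProfile:
    """Centred moving average with edge replication; length unchanged."""
    n = len(p)
    if window % 2 == 0 or window < 1:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    if window > n // 2:
        raise ParameterError(f"window {window} too large for profile of {n} samples")
    if window == 1:
        return p
    half = window // 2
    padded = np.pad(p.values, half, mode="edge")
    kernel = np.full(window, 1.0 / window)
    smoothed = np.convolve(padded, kernel, mode="valid")
    return IntensityProfile(values=smoothed, origin=p.origin, direction=p.direction)


def differentiate(p: IntensityProfile) -> np.ndarray:
    """dF/dx by central differences (one-sided at the ends); unit spacing."""
    if len(p) < 3:
        raise ParameterError("need at least 3 samples to differentiate")
    return np.gradient(p.values)


def _candidate_peaks(x: np.ndarray) -> List[int]:
    """Indices of strict local maxima; a plateau maximum reports its
    leftmost sample.  Signal endpoints are never peaks."""
    n = x.size
    peaks: List[int] = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            # walk the plateau of equal values starting at i
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return peaks


def _prominence(x: np.ndarray, i: int) -> float:
    """Height of peak i above the higher of its two surrounding minima.

    Scanning stops on either side at the first sample strictly higher
    than the peak (or the signal border, which then acts as the base)."""
    h = x[i]
    left_min = h
    for j in range(i - 1, -1, -1):
        if x[j] > h:
            break
        left_min = min(left_min, x[j])
    right_min = h
    for j in range(i + 1, x.size):
        if x[j] > h:
            break
        right_min = min(right_min, x[j])
    return float(h - max(left_min, right_min))


def detect_peaks(
    signal: Sequence[float],
    min_prominence: float = 0.0,
    min_separation: int = 1,
) -> List[int]:
    """Local maxima filtered by prominence and mutual separation.

    Peaks are strict local maxima (plateau maxima report the leftmost
    plateau sample) whose prominence is at least ``min_prominence``.  When
    two qualifying peaks lie closer than ``min_separation`` samples, the
    taller survives; equal heights keep the leftmost.  Returned indices
    are in increasing order.
    """
    if min_prominence < 0:
        raise ParameterError("min_prominence must be >= 0")
    if min_separation < 1:
        raise ParameterError("min_separation must be >= 1")
    x = np.asarray(signal, dtype=np.float64)
    cands = [i for i in _candidate_peaks(x) if _prominence(x, i) >= min_prominence]
    if min_separation > 1 and len(cands) > 1:
        order = sorted(cands, key=lambda i: (-x[i], i))
        kept: List[int] = []
        for i in order:
            if all(abs(i - k) >= min_separation for k in kept):
                kept.append(i)
        cands = sorted(kept)
    return cands
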