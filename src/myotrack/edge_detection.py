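"""Vessel wall edge localization on 1-D intensity profiles.

An edge is defined as the extremum of the intensity derivative dF/dx
(the steepest point of the transition), located to sub-pixel precision.
Two detectors cover the supported imaging modalities:

* brightfield / en-face strips: dark walls on a bright background, edges
  are peaks of -dF/dx (entering a wall) and +dF/dx (leaving one);
* fluorescence / B-mode ultrasound: walls are two bright bands on a dark
  lumen and background, so the band apexes are found on F itself and the
  four edges on the flanks of those bands.

Prominence thresholds are relative to the profile (robust SD of the
derivative; fraction of the dynamic range) so a single default behaves
the same for 8-bit and 16-bit inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model import MyotrackError, ParameterError
from .profiles import IntensityProfile, detect_peaks, differentiate, smooth_profile

__all__ = [
    "EdgeSet",
    "DetectionParams",
    "NoEdgesError",
    "refine_subpixel",
    "find_edges_brightfield",
    "find_edges_fluorescence",
    "find_edges",
]


class NoEdgesError(MyotrackError):
    """Raised when a profile does not contain a detectable vessel."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable edge-detection parameters.

    smooth_window:
        Moving-average window (samples, odd) applied before differencing.
    k:
        Prominence threshold for derivative peaks, in multiples of the
        robust SD (1.4826 x MAD) of dF/dx.
    band_prominence:
        Fluorescence band prominence as a fraction of the profile's
        dynamic range.
    min_separation:
        Minimum distance between detected derivative peaks, in samples.
    invert:
        Flip the profile sign before detection, for images whose contrast
        is reversed relative to the modality's usual presentation.
    """

    smooth_window: int = 5
    k: float = 3.0
    band_prominence: float = 0.25
    min_separation: int = 5
    invert: bool = False


@dataclass(frozen=True)
class EdgeSet:
    """Sub-pixel wall-edge positions along a profile, in sample units."""

    outer_left: float
    outer_right: float
    inner_left: Optional[float] = None
    inner_right: Optional[float] = None
    mode: str = "brightfield"
    band_apexes: Optional[tuple] = None  # diagnostics (fluorescence)

    def __post_init__(self) -> None:
        if not (self.outer_left < self.outer_right):
            raise NoEdgesError(
                f"outer edges out of order: {self.outer_left} >= {self.outer_right}"
            )
        if (self.inner_left is None) != (self.inner_right is None):
            raise NoEdgesError("inner edges must be present or absent together")
        if self.inner_left is not None:
            if not (
                self.outer_left < self.inner_left < self.inner_right < self.outer_right
            ):
                raise NoEdgesError("edge ordering violated")
        if self.mode == "en_face" and self.inner_left is not None:
            raise NoEdgesError("en_face edges never carry inner positions")

    @property
    def has_inner(self) -> bool:
        return self.inner_left is not None

    def outer_span(self) -> float:
        return self.outer_right - self.outer_left

    def inner_span(self) -> Optional[float]:
        if not self.has_inner:
            return None
        return self.inner_right - self.inner_left


def refine_subpixel(signal: np.ndarray, peak_index: int) -> float:
    """Sub-pixel apex via a parabola through the peak and its neighbours.

    The vertex abscissa is clamped to within half a sample of the peak;
    a degenerate (zero-curvature) triple or a boundary index returns the
    integer position unchanged.
    """
    x = np.asarray(signal, dtype=np.float64)
    i = int(peak_index)
    if i < 1 or i > x.size - 2:
        return float(i)
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(i)
    delta = 0.5 * (y0 - y2) / denom
    return float(i + np.clip(delta, -0.5, 0.5))


def _localize(signal: np.ndarray, idx: int) -> float:
    """Sub-pixel position of the extremum at idx of a derivative signal.

    A noise-free symmetric step yields a flat plateau in the sampled
    derivative whose true apex is the plateau centre, so plateaus are
    resolved to their midpoint; isolated apexes use the parabolic vertex.
    """
    x = np.asarray(signal, dtype=np.float64)
    lo = hi = int(idx)
    while lo - 1 >= 0 and x[lo - 1] == x[idx]:
        lo -= 1
    while hi + 1 < x.size and x[hi + 1] == x[idx]:
        hi += 1
    if hi > lo:
        return 0.5 * (lo + hi)
    return refine_subpixel(x, idx)


def _robust_sd(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    return float(1.4826 * mad)


def _derivative_peaks(d: np.ndarray, params: DetectionParams):
    """Qualifying peaks of +dF/dx and -dF/dx with a shared threshold."""
    maxabs = float(np.max(np.abs(d)))
    if maxabs <= 0:
        return [], []
    # noise-free profiles have zero MAD; fall back to a fixed fraction of
    # the strongest transition so the threshold stays relative either way
    thresh = max(params.k * _robust_sd(d), 0.1 * maxabs)
    pos = detect_peaks(d, min_prominence=thresh, min_separation=params.min_separation)
    neg = detect_peaks(-d, min_prominence=thresh, min_separation=params.min_separation)
    # prominence alone admits noise wiggles (a +3sd peak beside a -3sd dip
    # has ~6sd prominence); a real wall transition must also stand at a
    # meaningful fraction of the strongest transition in this profile
    floor = max(thresh, 0.2 * maxabs)
    pos = [i for i in pos if d[i] >= floor]
    neg = [i for i in neg if -d[i] >= floor]
    return pos, neg


def find_edges_brightfield(
    p: IntensityProfile,
    params: DetectionParams = DetectionParams(),
    search_inner: bool = True,
    mode: str = "brightfield",
) -> EdgeSet:
    """Edges of a dark-walled vessel on a bright background.

    The profile is smoothed, differentiated, and peaks of +-dF/dx are
    thresholded at ``k`` robust SDs.  The outer-left edge is the leftmost
    qualifying negative-going transition, the outer-right the rightmost
    positive-going one; the inner edges are the strongest opposite-sign
    transitions strictly inside, one per half.  Inner edges are omitted
    when no candidate qualifies (e.g. en-face strips).
    """
    sp = smooth_profile(p, params.smooth_window)
    d = differentiate(sp)
    pos, neg = _derivative_peaks(d, params)
    if not neg or not pos:
        raise NoEdgesError("no qualifying wall edges in profile")
    ol_i = neg[0]
    or_i = max(pos)
    if ol_i >= or_i:
        raise NoEdgesError("edge candidates out of order (no vessel spanned)")
    outer_left = _localize(-d, ol_i)
    outer_right = _localize(d, or_i)

    inner_left = inner_right = None
    if search_inner:
        mid = 0.5 * (ol_i + or_i)
        left_c = [i for i in pos if ol_i < i < or_i and i <= mid]
        right_c = [i for i in neg if ol_i < i < or_i and i > mid]
        if left_c and right_c:
            il_i = max(left_c, key=lambda i: d[i])
            ir_i = max(right_c, key=lambda i: -d[i])
            il = _localize(d, il_i)
            ir = _localize(-d, ir_i)
            if outer_left < il < ir < outer_right:
                inner_left, inner_right = il, ir
    return EdgeSet(
        outer_left=outer_left,
        outer_right=outer_right,
        inner_left=inner_left,
        inner_right=inner_right,
        mode=mode,
    )


def find_edges_fluorescence(
    p: IntensityProfile,
    params: DetectionParams = DetectionParams(),
    mode: str = "fluorescence",
) -> EdgeSet:
    """Edges of bright-walled vessels (fluorescence, B-mode ultrasound).

    Wall bands are found as peaks of the smoothed intensity itself with
    prominence at least ``band_prominence`` of the dynamic range; at
    least two bands are required.  Each outer edge is the steepest point
    on the outer flank of its band, each inner edge the steepest point on
    the lumen-facing flank.
    """
    sp = smooth_profile(p, params.smooth_window)
    f = sp.values
    rng = float(f.max() - f.min())
    if rng <= 0:
        raise NoEdgesError("flat profile")
    bands = detect_peaks(
        f,
        min_prominence=params.band_prominence * rng,
        min_separation=params.min_separation,
    )
    if len(bands) < 2:
        raise NoEdgesError(f"need two wall bands, found {len(bands)}")
    L, R = bands[0], bands[-1]
    mid = (L + R) // 2
    d = differentiate(sp)

    def _argext(sig: np.ndarray, lo: int, hi: int) -> int:
        if hi <= lo:
            raise NoEdgesError("empty flank search region")
        return lo + int(np.argmax(sig[lo:hi]))

    ol_i = _argext(d, 0, L + 1)            # rising onto left band
    il_i = _argext(-d, L, mid + 1)         # falling into lumen
    ir_i = _argext(d, mid, R + 1)          # rising onto right band
    or_i = _argext(-d, R, len(sp))         # falling to background
    return EdgeSet(
        outer_left=_localize(d, ol_i),
        inner_left=_localize(-d, il_i),
        inner_right=_localize(d, ir_i),
        outer_right=_localize(-d, or_i),
        mode=mode,
        band_apexes=(_localize(f, L), _localize(f, R)),
    )


def find_edges(
    p: IntensityProfile, mode: str, params: DetectionParams = DetectionParams()
) -> EdgeSet:
    """Dispatch to the modality-appropriate detector.

    brightfield uses the dark-wall detector; fluorescence and ultrasound
    the bright-band detector; en_face the dark-wall detector with the
    inner-edge search disabled (a flat strip has no lumen edges).  The
    ``invert`` flag negates the profile first for reversed contrast.
    """
    if params.invert:
        p = IntensityProfile(
            values=-p.values, origin=p.origin, direction=p.direction
        )
    if mode == "brightfield":
        return find_edges_brightfield(p, params)
    if mode in ("fluorescence", "ultrasound"):
        return find_edges_fluorescence(p, params, mode=mode)
    if mode == "en_face":
        return find_edges_brightfield(p, params, search_inner=False, mode="en_face")
    raise ParameterError(f"unknown mode {mode!r}")
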