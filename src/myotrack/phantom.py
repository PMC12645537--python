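"""Synthetic vessel phantoms with exact ground truth.

Phantoms emulate the image appearances the tracker supports: dark-walled
tubes on a bright background (transmitted-light brightfield), bright
wall bands on a dark lumen and background (fluorescence-labelled vessels
and B-mode ultrasound), flat two-edged strips (en-face mounted vessels)
and branched three-arm geometries for multi-line tracking.

Walls are rendered with a one-pixel anti-aliased (distance-smoothed)
boundary before optical blur, so the mid-transition of the intensity —
the point a derivative-peak edge detector localizes — falls exactly at
the analytic radius.  That makes sub-pixel accuracy claims testable:
the ground truth written next to each frame is exact by construction.

Per-frame noise is seeded as ``seed + frame_index`` so stacks are
reproducible frame-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .model import Calibration, FrameStack, MyotrackError, ParameterError, TrackLine

__all__ = [
    "PhantomSpec",
    "DegeneratePhantomError",
    "GeometryError",
    "render_frame",
    "make_stack",
    "make_branched_stack",
    "branched_track_lines",
    "simulate_dynamics",
    "PressureDiameterModel",
]

GEOMETRIES = ("straight", "branched3", "strip")
# default Y geometry: one arm left, two arms fanning right
DEFAULT_ARM_ANGLES = (180.0, 45.0, -45.0)


class DegeneratePhantomError(MyotrackError):
    """Wall too thin to render at the requested scale."""


class GeometryError(MyotrackError):
    """Branched geometry invalid (arms overlap a measurement region)."""


@dataclass
class PhantomSpec:
    """Full description of a synthetic vessel stack.

    ``od_track`` is the ground-truth outer diameter per frame in microns:
    shape (n_frames,) for straight/strip geometry, (3, n_frames) for
    branched3.  ``id_fraction`` is the inner/outer diameter ratio (a
    scalar or per-frame array); strips have no lumen and ignore it.
    ``intensities`` is (background, wall, lumen) on a nominal 0-255
    scale; pick bright background/dark wall for brightfield and the
    converse for fluorescence.  ``axis_angle`` is the vessel axis
    direction in degrees from the image x-axis.
    """

    geometry: str
    frame_size: Tuple[int, int]  # (width, height) px
    od_track: np.ndarray  # um
    calibration: Calibration
    id_fraction: float = 0.6
    intensities: Tuple[float, float, float] = (200.0, 50.0, 150.0)
    axis_angle: float = 90.0
    arm_angles: Tuple[float, float, float] = DEFAULT_ARM_ANGLES
    psf_sigma: float = 0.8
    noise_sd: float = 0.0
    n_frames: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ParameterError(f"unknown geometry {self.geometry!r}")
        self.od_track = np.atleast_1d(np.asarray(self.od_track, dtype=np.float64))
        if self.geometry == "branched3":
            if self.od_track.ndim == 1:
                self.od_track = np.tile(self.od_track, (3, 1))
            if self.od_track.shape[0] != 3:
                raise ParameterError("branched3 needs exactly 3 od_tracks")
            nf = self.od_track.shape[1]
        else:
            if self.od_track.ndim != 1:
                raise ParameterError("straight/strip geometry takes a 1-D od_track")
            nf = self.od_track.shape[0]
        if self.n_frames is None:
            self.n_frames = nf
        if self.n_frames != nf:
            raise ParameterError("n_frames inconsistent with od_track length")
        if not np.all(self.od_track > 0):
            raise ParameterError("od_track must be positive everywhere")
        if not (0.0 < self.id_fraction < 1.0):
            raise ParameterError("id_fraction must lie in (0, 1)")

    @property
    def shape(self) -> Tuple[int, int]:
        """(rows, cols) array shape of a rendered frame."""
        w, h = self.frame_size
        return (int(h), int(w))

    @property
    def center(self) -> Tuple[float, float]:
        w, h = self.frame_size
        return ((w - 1) / 2.0, (h - 1) / 2.0)


def _coverage(half_width_px: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Anti-aliased inside-mask: 1 well inside, 0 outside, linear one-px
    ramp centred on the boundary (mid-transition exactly at the radius)."""
    return np.clip(half_width_px - dist + 0.5, 0.0, 1.0)


def _check_wall(od_px: float, id_px: float) -> None:
    if (od_px - id_px) / 2.0 < 2.0:
        raise DegeneratePhantomError(
            f"wall of {(od_px - id_px) / 2.0:.2f} px cannot be resolved; "
            "reduce id_fraction or the pixel scale"
        )


def _pixel_grid(spec: PhantomSpec):
    h, w = spec.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    return xs, ys


def _axis_distance(spec: PhantomSpec, xs, ys) -> np.ndarray:
    cx, cy = spec.center
    th = math.radians(spec.axis_angle)
    nx, ny = -math.sin(th), math.cos(th)
    return np.abs((xs - cx) * nx + (ys - cy) * ny)


def _ray_distance(xs, ys, jx, jy, angle_deg) -> np.ndarray:
    """Distance from each pixel to the half-line from (jx, jy)."""
    th = math.radians(angle_deg)
    ux, uy = math.cos(th), math.sin(th)
    dx, dy = xs - jx, ys - jy
    t = np.clip(dx * ux + dy * uy, 0.0, None)
    return np.hypot(dx - t * ux, dy - t * uy)


def render_frame(spec: PhantomSpec, frame_index: int) -> Tuple[np.ndarray, dict]:
    """Render one frame and return it with its exact ground truth.

    Ground truth is a dict with ``od_um`` and (when a lumen exists)
    ``id_um``; for branched geometry both are per-arm tuples.
    """
    if not (0 <= frame_index < spec.n_frames):
        raise ParameterError(f"frame_index {frame_index} out of range")
    bg, wall, lumen = spec.intensities
    scale = spec.calibration.scale
    xs, ys = _pixel_grid(spec)

    if spec.geometry == "branched3":
        jx, jy = spec.center
        od_um = spec.od_track[:, frame_index]
        m_o = np.zeros(spec.shape)
        m_i = np.zeros(spec.shape)
        truth_id = []
        for arm in range(3):
            od_px = od_um[arm] / scale
            id_px = od_px * spec.id_fraction
            _check_wall(od_px, id_px)
            d = _ray_distance(xs, ys, jx, jy, spec.arm_angles[arm])
            m_o = np.maximum(m_o, _coverage(od_px / 2.0, d))
            m_i = np.maximum(m_i, _coverage(id_px / 2.0, d))
            truth_id.append(od_um[arm] * spec.id_fraction)
        truth = {"od_um": tuple(od_um), "id_um": tuple(truth_id)}
    else:
        od_um = float(spec.od_track[frame_index])
        od_px = od_um / scale
        d = _axis_distance(spec, xs, ys)
        m_o = _coverage(od_px / 2.0, d)
        if spec.geometry == "strip":
            m_i = np.zeros(spec.shape)
            truth = {"od_um": od_um}
        else:
            id_px = od_px * spec.id_fraction
            _check_wall(od_px, id_px)
            m_i = _coverage(id_px / 2.0, d)
            truth = {"od_um": od_um, "id_um": od_um * spec.id_fraction}

    img = bg * (1.0 - m_o) + wall * (m_o - m_i) + lumen * m_i
    if spec.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.psf_sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + frame_index)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return img, truth


def make_stack(spec: PhantomSpec) -> Tuple[FrameStack, List[dict]]:
    """Render the whole stack; returns the FrameStack and per-frame truth."""
    frames = []
    truths = []
    for fi in range(spec.n_frames):
        img, truth = render_frame(spec, fi)
        frames.append(img)
        truths.append(truth)
    stack = FrameStack(
        frames=np.stack(frames), frame_interval=1.0, calibration=spec.calibration
    )
    return stack, truths


def branched_track_lines(
    spec: PhantomSpec,
    standoff_px: float = 60.0,
    margin_px: float = 25.0,
    mode: str = "brightfield",
    n_scanlines_halfwidth: float = 2.0,
) -> List[TrackLine]:
    """Segment track lines crossing each arm at a standoff from the junction.

    Each line is perpendicular to its arm, centred ``standoff_px`` from
    the junction, and long enough to show background beyond the largest
    outer diameter of that arm.  Raises GeometryError when another arm
    intrudes into a line's measurement region.
    """
    if spec.geometry != "branched3":
        raise ParameterError("branched_track_lines needs branched3 geometry")
    jx, jy = spec.center
    scale = spec.calibration.scale
    lines = []
    for arm in range(3):
        max_od_px = float(np.max(spec.od_track[arm])) / scale
        half_len = max_od_px / 2.0 + margin_px
        th = math.radians(spec.arm_angles[arm])
        ux, uy = math.cos(th), math.sin(th)
        nx, ny = -uy, ux
        cx, cy = jx + standoff_px * ux, jy + standoff_px * uy
        p0 = (cx - half_len * nx, cy - half_len * ny)
        p1 = (cx + half_len * nx, cy + half_len * ny)
        # the measurement region must not touch the other arms
        for other in range(3):
            if other == arm:
                continue
            other_r = float(np.max(spec.od_track[other])) / scale / 2.0
            for px_, py_ in (p0, (cx, cy), p1):
                d = _point_ray_distance(px_, py_, jx, jy, spec.arm_angles[other])
                if d < other_r + 4.0 * max(spec.psf_sigma, 1.0):
                    raise GeometryError(
                        f"arm {other} intrudes into the measurement region of arm {arm}"
                    )
        lines.append(
            TrackLine(
                id=arm,
                kind="segment",
                geometry=(p0[0], p0[1], p1[0], p1[1]),
                half_width=n_scanlines_halfwidth,
                mode=mode,
            )
        )
    return lines


def _point_ray_distance(px, py, jx, jy, angle_deg) -> float:
    th = math.radians(angle_deg)
    ux, uy = math.cos(th), math.sin(th)
    dx, dy = px - jx, py - jy
    t = max(dx * ux + dy * uy, 0.0)
    return math.hypot(dx - t * ux, dy - t * uy)


def make_branched_stack(spec: PhantomSpec) -> Tuple[FrameStack, np.ndarray]:
    """Render a branched stack; returns the stack and the (3, n_frames)
    per-arm ground-truth outer diameters in microns."""
    if spec.geometry != "branched3":
        raise ParameterError("make_branched_stack needs branched3 geometry")
    stack, _ = make_stack(spec)
    return stack, spec.od_track.copy()


# ---------------------------------------------------------------------------
# diameter dynamics (test fixtures, not physiology claims)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass(frozen=True)
class PressureDiameterModel:
    """Passive/active pressure-diameter relation used as a dynamics fixture.

    The passive (fully relaxed, e.g. zero-calcium) diameter saturates
    exponentially with pressure::

        OD_p(P) = d0 * (1 - a * exp(-P / pc))

    The active diameter subtracts a myogenic tone term that is exactly
    zero up to ``tone_threshold`` and rises smoothly over ``tone_width``
    to ``tone_max``, emulating sustained constriction of resistance
    arteries at higher transmural pressures.
    """

    d0_um: float = 180.0
    a: float = 0.65
    pc_mmHg: float = 30.0
    tone_max_um: float = 55.0
    tone_threshold_mmHg: float = 60.0
    tone_width_mmHg: float = 60.0
    active: bool = True

    def __post_init__(self) -> None:
        if not (self.pc_mmHg > 0):
            raise ParameterError("pc_mmHg must be positive")

    def passive(self, pressure_mmHg) -> np.ndarray:
        p = np.asarray(pressure_mmHg, dtype=np.float64)
        return self.d0_um * (1.0 - self.a * np.exp(-p / self.pc_mmHg))

    def tone(self, pressure_mmHg) -> np.ndarray:
        p = np.asarray(pressure_mmHg, dtype=np.float64)
        return self.tone_max_um * _smoothstep(
            (p - self.tone_threshold_mmHg) / self.tone_width_mmHg
        )

    def od(self, pressure_mmHg) -> np.ndarray:
        od = self.passive(pressure_mmHg)
        if self.active:
            od = od - self.tone(pressure_mmHg)
        return od


def simulate_dynamics(kind: str, params: dict) -> np.ndarray:
    """Ground-truth outer-diameter time courses for phantom stacks.

    ``drug_step`` relaxes the diameter exponentially toward a new target
    after each event, emulating agonist responses (vasoconstriction
    followed by endothelium-dependent dilatation)::

        OD(t) = target + (OD(t_event) - target) * exp(-(t - t_event)/tau)

    params: baseline_um, n_frames, frame_interval_s,
    events = [(time_s, target_um, tau_s), ...].

    ``pressure_curve`` maps a per-frame pressure trace through a
    PressureDiameterModel; params: pressures_mmHg, model (optional).
    """
    if kind == "drug_step":
        n = int(params["n_frames"])
        dt = float(params.get("frame_interval_s", 1.0))
        baseline = float(params["baseline_um"])
        events = sorted(params.get("events", []), key=lambda e: e[0])
        for _, _, tau in events:
            if not (tau > 0):
                raise ParameterError("event time constant tau must be positive")
        times = np.arange(n) * dt
        od = np.full(n, baseline)
        # piecewise-analytic: the value at each event time comes from the
        # closed form of the preceding segment, so sampled values are exact
        v0, t0, target0, tau0 = baseline, None, None, None
        for t_ev, target, tau in events:
            if t0 is not None:
                v0 = target0 + (v0 - target0) * math.exp(-(t_ev - t0) / tau0)
            t0, target0, tau0 = t_ev, float(target), float(tau)
            idx = times >= t_ev
            od[idx] = target0 + (v0 - target0) * np.exp(-(times[idx] - t_ev) / tau0)
        return od
    if kind == "pressure_curve":
        model = params.get("model", PressureDiameterModel())
        pressures = np.asarray(params["pressures_mmHg"], dtype=np.float64)
        return model.od(pressures)
    raise ParameterError(f"unknown dynamics kind {kind!r}")
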