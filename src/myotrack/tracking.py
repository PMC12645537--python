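"""Per-frame, per-line diameter measurement and whole-stack tracking.

Each track line contributes several parallel scanline profiles per
frame.  Profiles are measured independently, outliers (side branches,
adherent tissue crossing one scanline) are rejected against the per-line
median by a 3xMAD rule, and the survivors are aggregated by median.  A
temporal filter then guards the frame-to-frame trace: measurements that
jump implausibly relative to the recent rolling median are replaced by
the last accepted value and marked ``held`` so downstream analysis can
exclude them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    Calibration,
    DomainError,
    FrameStack,
    ParameterError,
    TrackLine,
    px_to_um,
    validate_lines,
)
from .edge_detection import DetectionParams, NoEdgesError, find_edges
from .profiles import extract_profile, scanline_offsets

__all__ = [
    "TrackParams",
    "DiameterRecord",
    "ResultTable",
    "measure_line",
    "track_stack",
    "equivalent_diameter",
    "summarize_reactivity",
]


@dataclass(frozen=True)
class TrackParams:
    """Tracking configuration: edge detection plus quality control.

    mad_multiplier:
        Scanline outer diameters further than this many MADs from the
        per-line median are discarded before aggregation.
    k_frames:
        Temporal filter window: rolling median of the previous accepted
        measurements a new value is compared against.
    max_jump_fraction:
        Largest tolerated fractional deviation of a new outer diameter
        from that rolling median; larger jumps are held.
    """

    detection: DetectionParams = field(default_factory=DetectionParams)
    mad_multiplier: float = 3.0
    k_frames: int = 5
    max_jump_fraction: float = 0.25


@dataclass(frozen=True)
class DiameterRecord:
    """One line's measurement on one frame (microns)."""

    frame_index: int
    time: float
    line_id: int
    outer_um: Optional[float]
    inner_um: Optional[float] = None
    wall_um: Optional[float] = None
    n_profiles_used: int = 0
    status: str = "tracked"
    pressure_mmHg: Optional[float] = None
    temperature_C: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in ("tracked", "held", "failed"):
            raise ParameterError(f"unknown status {self.status!r}")
        if self.status == "tracked" and not (self.outer_um and self.outer_um > 0):
            raise ParameterError("tracked records need a positive outer diameter")
        if self.inner_um is not None and self.outer_um is not None:
            if not (0 < self.inner_um < self.outer_um):
                raise ParameterError("inner diameter must lie in (0, outer)")


@dataclass
class ResultTable:
    """Diameter records ordered by (frame, line) plus a timestamped event log."""

    records: List[DiameterRecord] = field(default_factory=list)
    events: List[tuple] = field(default_factory=list)  # (time, label, pressure, temp)

    def add_record(self, rec: DiameterRecord) -> None:
        self.records.append(rec)

    def add_event(
        self,
        time: float,
        label: str,
        pressure_mmHg: Optional[float] = None,
        temperature_C: Optional[float] = None,
    ) -> None:
        if self.events and time < self.events[-1][0]:
            raise ParameterError("event times must be non-decreasing")
        self.events.append((time, label, pressure_mmHg, temperature_C))

    def validate(self) -> None:
        seen = set()
        for r in self.records:
            key = (r.frame_index, r.line_id)
            if key in seen:
                raise ParameterError(f"duplicate record for {key}")
            seen.add(key)

    def trace(self, line_id: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(times, outer_um, statuses) for one line, NaN where unmeasured."""
        recs = [r for r in self.records if r.line_id == line_id]
        recs.sort(key=lambda r: r.frame_index)
        t = np.array([r.time for r in recs])
        d = np.array(
            [r.outer_um if r.outer_um is not None else np.nan for r in recs]
        )
        s = np.array([r.status for r in recs])
        return t, d, s


def _measure_profiles(frame, line, params):
    """Edge sets for every scanline of a line; failures are dropped."""
    out = []
    for off in scanline_offsets(line):
        try:
            p = extract_profile(frame, line, off)
            es = find_edges(p, line.mode, params.detection)
        except (NoEdgesError, ParameterError):
            continue
        out.append(es)
    return out


def measure_line(
    frame: np.ndarray,
    line: TrackLine,
    cal: Calibration,
    params: TrackParams = TrackParams(),
    frame_index: int = 0,
    time: float = 0.0,
) -> DiameterRecord:
    """Measure one line on one frame with robust scanline aggregation.

    Per-profile outer diameters more than ``mad_multiplier`` MADs from
    the median are rejected; survivors are aggregated by median and
    converted to microns.  The record is ``tracked`` only when at least
    half the line's scanlines survive.
    """
    n_scan = len(scanline_offsets(line))
    edge_sets = _measure_profiles(frame, line, params)
    failed = DiameterRecord(
        frame_index=frame_index,
        time=time,
        line_id=line.id,
        outer_um=None,
        status="failed",
    )
    if not edge_sets:
        return failed
    od = np.array([es.outer_span() for es in edge_sets])
    med = np.median(od)
    mad = np.median(np.abs(od - med))
    keep = np.abs(od - med) <= params.mad_multiplier * mad + 1e-9
    survivors = [es for es, k in zip(edge_sets, keep) if k]
    if len(survivors) < math.ceil(n_scan / 2):
        return failed

    outer_px = float(np.median([es.outer_span() for es in survivors]))
    inner_spans = [es.inner_span() for es in survivors if es.has_inner]
    inner_px = float(np.median(inner_spans)) if inner_spans else None
    walls = [
        0.5 * ((es.inner_left - es.outer_left) + (es.outer_right - es.inner_right))
        for es in survivors
        if es.has_inner
    ]
    wall_px = float(np.median(walls)) if walls else None
    return DiameterRecord(
        frame_index=frame_index,
        time=time,
        line_id=line.id,
        outer_um=px_to_um(cal, outer_px),
        inner_um=px_to_um(cal, inner_px) if inner_px is not None else None,
        wall_um=px_to_um(cal, wall_px) if wall_px is not None else None,
        n_profiles_used=len(survivors),
        status="tracked",
    )


def track_stack(
    stack: FrameStack,
    lines: Sequence[TrackLine],
    params: TrackParams = TrackParams(),
) -> ResultTable:
    """Track every line through every frame with temporal quality control.

    A tracked value deviating from the rolling median of the previous
    ``k_frames`` accepted values by more than ``max_jump_fraction`` of
    that median — or an outright failed measurement — is replaced by the
    last accepted record's values with status ``held``.
    """
    validate_lines(lines, stack.frame_shape)
    table = ResultTable()
    history = {ln.id: [] for ln in lines}  # accepted outer_um per line
    last_ok: dict = {ln.id: None for ln in lines}
    for fi in range(len(stack)):
        t = fi * stack.frame_interval
        frame = stack.frames[fi]
        for ln in lines:
            rec = measure_line(
                frame, ln, stack.calibration, params, frame_index=fi, time=t
            )
            accept = rec.status == "tracked"
            if accept and history[ln.id]:
                recent = history[ln.id][-params.k_frames :]
                roll = float(np.median(recent))
                if roll > 0 and abs(rec.outer_um - roll) > params.max_jump_fraction * roll:
                    accept = False
            if accept:
                history[ln.id].append(rec.outer_um)
                last_ok[ln.id] = rec
                table.add_record(rec)
            else:
                prev = last_ok[ln.id]
                if prev is None:
                    table.add_record(
                        DiameterRecord(
                            frame_index=fi,
                            time=t,
                            line_id=ln.id,
                            outer_um=None,
                            status="failed",
                        )
                    )
                else:
                    table.add_record(
                        DiameterRecord(
                            frame_index=fi,
                            time=t,
                            line_id=ln.id,
                            outer_um=prev.outer_um,
                            inner_um=prev.inner_um,
                            wall_um=prev.wall_um,
                            n_profiles_used=0,
                            status="held",
                        )
                    )
    table.validate()
    return table


def equivalent_diameter(width_um: float, convention: str = "width") -> float:
    """Equivalent pressurized-vessel diameter of an en-face strip width.

    ``width`` reports the measured strip width unchanged;
    ``circumference`` reads the strip width as the opened-out vessel
    circumference and returns width / pi.
    """
    if not (width_um > 0):
        raise DomainError(f"width must be positive, got {width_um!r}")
    if convention == "width":
        return float(width_um)
    if convention == "circumference":
        return float(width_um) / math.pi
    raise ParameterError(f"unknown convention {convention!r}")


def summarize_reactivity(
    times: Sequence[float],
    diameters: Sequence[float],
    baseline_window: Tuple[float, float],
    response_window: Tuple[float, float],
    direction: str = "dilatation",
) -> float:
    """Percent diameter change of a response relative to a baseline.

    Returns ``100 * (peak(response) - mean(baseline)) / mean(baseline)``
    where the peak is the maximum for dilatation (e.g. flow-mediated
    dilatation) and the minimum for constriction.  Windows are half-open
    time intervals ``[start, stop)`` and must not overlap.
    """
    t = np.asarray(times, dtype=np.float64)
    d = np.asarray(diameters, dtype=np.float64)
    b0, b1 = baseline_window
    r0, r1 = response_window
    if max(b0, r0) < min(b1, r1):
        raise ParameterError("baseline and response windows overlap")
    bmask = (t >= b0) & (t < b1) & np.isfinite(d)
    rmask = (t >= r0) & (t < r1) & np.isfinite(d)
    if not bmask.any() or not rmask.any():
        raise ParameterError("each window must contain at least one measurement")
    base = float(np.mean(d[bmask]))
    if direction == "constriction":
        peak = float(np.min(d[rmask]))
    elif direction == "dilatation":
        peak = float(np.max(d[rmask]))
    else:
        raise ParameterError(f"unknown direction {direction!r}")
    return 100.0 * (peak - base) / base
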