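"""Automated pressure-step protocols against a simulated pressure servo.

A protocol is a staircase of pressure setpoints (e.g. 20 to 100 mmHg in
20 mmHg steps for mouse mesenteric arteries, or up to 200 mmHg for rat)
each held for a fixed equilibration time.  The servo is modelled as a
first-order system relaxing toward the commanded setpoint, optionally
carrying a sinusoidal oscillation that mimics pulsatile pressure at up
to the murine heart rate (~400 cycles/min).  Running a protocol renders
phantom frames from a pressure-diameter model, tracks them, and logs a
"pressure set" event at every level transition — the fully simulated
counterpart of an automated myograph experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .model import Calibration, FrameStack, ParameterError
from .phantom import PhantomSpec, PressureDiameterModel, make_stack
from .tracking import ResultTable, TrackParams, measure_line
from .model import TrackLine

__all__ = [
    "Oscillation",
    "PressureProtocol",
    "PressureLevel",
    "SimulatedServo",
    "build_step_protocol",
    "simulate_pressure_trace",
    "run_protocol",
]

MAX_OSCILLATION_PER_MIN = 400.0


@dataclass(frozen=True)
class Oscillation:
    """Sinusoidal pressure modulation (peak amplitude, cycles per minute)."""

    amplitude_mmHg: float
    rate_per_min: float

    def __post_init__(self) -> None:
        if self.amplitude_mmHg < 0:
            raise ParameterError("oscillation amplitude must be >= 0")
        if not (0 < self.rate_per_min <= MAX_OSCILLATION_PER_MIN):
            raise ParameterError(
                f"oscillation rate must be in (0, {MAX_OSCILLATION_PER_MIN}] per minute"
            )


@dataclass(frozen=True)
class PressureProtocol:
    """Stepwise pressure staircase: start..stop in ``step`` mmHg increments,
    each level held ``hold`` seconds."""

    start: float
    stop: float
    step: float
    hold: float = 120.0
    oscillation: Optional[Oscillation] = None

    def __post_init__(self) -> None:
        if not (self.step > 0):
            raise ParameterError("step must be positive")
        if not (self.hold > 0):
            raise ParameterError("hold must be positive")
        if self.start < 0 or self.stop < 0:
            raise ParameterError("pressures must be non-negative")


@dataclass(frozen=True)
class PressureLevel:
    pressure_mmHg: float
    hold_s: float
    partial: bool = False  # final step smaller than the protocol's step


def build_step_protocol(
    start: float, stop: float, step: float, hold: float = 120.0
) -> List[PressureLevel]:
    """Expand a staircase into its ordered levels.

    The direction is inferred from ``stop - start`` and the stop pressure
    is always included; when the step does not divide the span exactly
    the last level is a partial step, flagged as such.
    """
    proto = PressureProtocol(start=start, stop=stop, step=step, hold=hold)
    if start == stop:
        return [PressureLevel(float(start), hold)]
    sign = 1.0 if stop > start else -1.0
    levels: List[PressureLevel] = []
    n_full = int(math.floor(abs(stop - start) / step + 1e-9))
    for i in range(n_full + 1):
        levels.append(PressureLevel(float(start + sign * i * step), hold))
    if abs(levels[-1].pressure_mmHg - stop) > 1e-9:
        levels.append(PressureLevel(float(stop), hold, partial=True))
    return levels


@dataclass
class SimulatedServo:
    """First-order pressure servo: the line pressure relaxes toward the
    active setpoint with the given time constant; readings optionally
    carry Gaussian sensor noise."""

    current_pressure: float = 0.0
    time_constant: float = 2.0
    sensor_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.time_constant > 0):
            raise ParameterError("time_constant must be positive")
        if self.current_pressure < 0:
            raise ParameterError("pressure must be >= 0")

    def advance(self, setpoint: float, dt: float) -> float:
        """Advance the line pressure by dt toward the setpoint (exact
        first-order update) and return the new true pressure."""
        a = math.exp(-dt / self.time_constant)
        self.current_pressure = setpoint + (self.current_pressure - setpoint) * a
        return self.current_pressure

    def read(self, rng: Optional[np.random.Generator] = None) -> float:
        p = self.current_pressure
        if self.sensor_noise_sd > 0 and rng is not None:
            p += rng.normal(0.0, self.sensor_noise_sd)
        return p


def _setpoint_schedule(
    protocol: PressureProtocol, times: np.ndarray
) -> Tuple[np.ndarray, List[Tuple[float, float]]]:
    """Base setpoint at each time plus the (time, setpoint) transitions."""
    levels = build_step_protocol(
        protocol.start, protocol.stop, protocol.step, protocol.hold
    )
    bounds = np.cumsum([lv.hold_s for lv in levels])
    sp = np.empty_like(times)
    transitions = []
    t_start = 0.0
    for lv, t_end in zip(levels, bounds):
        mask = (times >= t_start - 1e-12) & (times < t_end - 1e-12)
        sp[mask] = lv.pressure_mmHg
        transitions.append((float(t_start), float(lv.pressure_mmHg)))
        t_start = float(t_end)
    sp[times >= bounds[-1] - 1e-12] = levels[-1].pressure_mmHg
    return sp, transitions


def simulate_pressure_trace(
    protocol: PressureProtocol,
    servo: SimulatedServo,
    dt: float,
    duration: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, List[Tuple[float, float]]]:
    """Simulate the servo through a protocol at a fixed time step.

    Returns (times, true pressures, transitions).  The oscillation term,
    when configured, rides on the setpoint: A * sin(2*pi*(rate/60)*t).
    """
    levels = build_step_protocol(
        protocol.start, protocol.stop, protocol.step, protocol.hold
    )
    total = duration if duration is not None else sum(lv.hold_s for lv in levels)
    n = int(round(total / dt))
    times = np.arange(n) * dt
    setpoints, transitions = _setpoint_schedule(protocol, times)
    if protocol.oscillation is not None:
        osc = protocol.oscillation
        f = osc.rate_per_min / 60.0
        setpoints = setpoints + osc.amplitude_mmHg * np.sin(2.0 * math.pi * f * times)
    pressures = np.empty(n)
    for i in range(n):
        # sample the line pressure at times[i], then relax toward the
        # setpoint active over [times[i], times[i+1])
        pressures[i] = servo.current_pressure
        servo.advance(float(setpoints[i]), dt)
    return times, pressures, transitions


def run_protocol(
    protocol: PressureProtocol,
    servo: SimulatedServo,
    dynamics: PressureDiameterModel,
    phantom_spec: PhantomSpec,
    line: TrackLine,
    track_params: TrackParams = TrackParams(),
    frame_interval: float = 1.0,
) -> ResultTable:
    """Run a fully simulated automated pressure-step experiment.

    At each frame interval the servo pressure advances toward the active
    setpoint, the pressure-diameter model gives the true outer diameter,
    a phantom frame is rendered and measured on ``line``, and the record
    (annotated with the pressure reading) is appended.  Every level
    transition logs a "pressure set" event.  Deterministic given the
    phantom seed and servo noise seed.
    """
    times, pressures, transitions = simulate_pressure_trace(
        protocol, servo, frame_interval
    )
    n = times.size
    od_track = dynamics.od(pressures)
    spec = replace_od_track(phantom_spec, od_track)
    stack, _ = make_stack(spec)
    rng = np.random.default_rng(spec.seed + 12345)

    table = ResultTable()
    trans_iter = iter(transitions)
    next_tr = next(trans_iter, None)
    for fi in range(n):
        t = times[fi]
        while next_tr is not None and next_tr[0] <= t + 1e-12:
            table.add_event(next_tr[0], "pressure set", pressure_mmHg=next_tr[1])
            next_tr = next(trans_iter, None)
        reading = pressures[fi]
        if servo.sensor_noise_sd > 0:
            reading += rng.normal(0.0, servo.sensor_noise_sd)
        rec = measure_line(
            stack.frames[fi],
            line,
            spec.calibration,
            track_params,
            frame_index=fi,
            time=float(t),
        )
        table.add_record(
            replace(rec, pressure_mmHg=float(reading))
        )
    table.validate()
    return table


def replace_od_track(spec: PhantomSpec, od_track: np.ndarray) -> PhantomSpec:
    """Copy of a straight/strip phantom spec with a new diameter track."""
    if spec.geometry == "branched3":
        raise ParameterError("run_protocol drives a single straight vessel")
    return PhantomSpec(
        geometry=spec.geometry,
        frame_size=spec.frame_size,
        od_track=np.asarray(od_track, dtype=np.float64),
        calibration=spec.calibration,
        id_fraction=spec.id_fraction,
        intensities=spec.intensities,
        axis_angle=spec.axis_angle,
        psf_sigma=spec.psf_sigma,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
    )
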