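"""Imposed tongue-palate motion sequences and force/frame alignment.

A test consists of a single vertical compression followed by alternating
horizontal shear strokes, each motion separated by a fixed rest.  Stages move
at piecewise-constant velocity (infinite acceleration), so trajectories are
piecewise linear and every timing quantity has a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotionProtocol",
    "Segment",
    "MotionSchedule",
    "ForceTrace",
    "Trajectory",
    "build_schedule",
    "sample_trajectory",
    "engineering_strain",
    "resample_force_to_frames",
    "phase_at",
]

VERTICAL = "vertical"
HORIZONTAL = "horizontal"

COMPRESSION = "compression"
REST = "rest"
SHEAR = "shear"


class ProtocolError(ValueError):
    """Raised for invalid protocol definitions or out-of-range queries."""


@dataclass(frozen=True)
class MotionProtocol:
    """Parameters of the imposed motion sequence.

    Defaults are the bench settings: 15 mm compression at 2.5 mm/s, four
    shear strokes of 5/10/10/10 mm at 2.5 mm/s, 1.5 s rests, 60 Hz video,
    25 kHz force sampling, 20 mm sample height.
    """

    compression_amplitude: float = 15.0
    compression_speed: float = 2.5
    shear_amplitudes: tuple[float, ...] = (5.0, 10.0, 10.0, 10.0)
    shear_speed: float = 2.5
    rest_duration: float = 1.5
    frame_rate: float = 60.0
    force_rate: float = 25_000.0
    sample_height: float = 20.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shear_amplitudes", tuple(float(a) for a in self.shear_amplitudes))
        if self.compression_amplitude < 0 or any(a < 0 for a in self.shear_amplitudes):
            raise ProtocolError("amplitudes must be non-negative")
        if self.compression_speed <= 0 or self.shear_speed <= 0:
            raise ProtocolError("speeds must be positive")
        if self.rest_duration < 0:
            raise ProtocolError("rest_duration must be non-negative")
        if self.frame_rate <= 0 or self.force_rate <= 0:
            raise ProtocolError("rates must be positive")
        if self.sample_height <= 0:
            raise ProtocolError("sample_height must be positive")


@dataclass(frozen=True)
class Segment:
    """One constant-velocity (possibly zero) interval of a schedule."""

    axis: str  # "vertical" | "horizontal"
    phase: str  # "compression" | "rest" | "shear"
    t_start: float
    t_end: float
    velocity: float  # mm/s, signed; 0 for rests

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ProtocolError("segment must have positive duration")


@dataclass(frozen=True)
class MotionSchedule:
    """Ordered, contiguous constant-velocity segments of both stages."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        for a, b in zip(self.segments, self.segments[1:]):
            if not np.isclose(a.t_end, b.t_start):
                raise ProtocolError("segments must be contiguous")

    @property
    def total_duration(self) -> float:
        return self.segments[-1].t_end if self.segments else 0.0

    @property
    def boundaries(self) -> np.ndarray:
        if not self.segments:
            return np.array([0.0])
        return np.array([self.segments[0].t_start] + [s.t_end for s in self.segments])

    def strokes(self) -> list[Segment]:
        """Shear segments in temporal order."""
        return [s for s in self.segments if s.phase == SHEAR]

    def position_at(self, t, axis: str):
        """Analytic stage position (mm) at time(s) ``t`` for one axis."""
        t = np.asarray(t, dtype=float)
        pos = np.zeros_like(t)
        for seg in self.segments:
            if seg.axis != axis or seg.velocity == 0.0:
                continue
            pos = pos + seg.velocity * np.clip(t - seg.t_start, 0.0, seg.duration)
        return pos if pos.ndim else float(pos)


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled normal/tangential force signals."""

    time: np.ndarray
    normal_force: np.ndarray
    tangential_force: np.ndarray
    rate: float

    SENSOR_RANGE_N = 50.0

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "normal_force", np.asarray(self.normal_force, dtype=float))
        object.__setattr__(self, "tangential_force", np.asarray(self.tangential_force, dtype=float))
        if time.size != self.normal_force.size or time.size != self.tangential_force.size:
            raise ValueError("force channels must match the time axis")
        if time.size > 1:
            dt = np.diff(time)
            if not np.allclose(dt, 1.0 / self.rate, rtol=1e-6, atol=1e-9):
                raise ValueError("force trace must be uniformly sampled at `rate`")


@dataclass(frozen=True)
class Trajectory:
    """Sampled stage positions with per-sample phase labels."""

    time: np.ndarray
    vertical: np.ndarray
    horizontal: np.ndarray
    phase: tuple[str, ...]


def build_schedule(protocol: MotionProtocol) -> MotionSchedule:
    """Lay out the full motion sequence as contiguous segments.

    Compression comes first, then a rest, then shear strokes of alternating
    sign (each followed by a rest, except the last stroke which ends the
    schedule).  Alternation keeps the horizontal excursion centered about
    the starting position.
    """
    segments: list[Segment] = []
    t = 0.0

    def _append(axis: str, phase: str, duration: float, velocity: float) -> None:
        nonlocal t
        end = t + duration
        if end > t:  # skip durations that underflow to nothing
            segments.append(Segment(axis, phase, t, end, velocity))
            t = end

    comp_dur = protocol.compression_amplitude / protocol.compression_speed
    _append(VERTICAL, COMPRESSION, comp_dur, protocol.compression_speed)

    sign = 1.0
    for amp in (a for a in protocol.shear_amplitudes if a > 0):
        _append(VERTICAL, REST, protocol.rest_duration, 0.0)
        before = len(segments)
        _append(HORIZONTAL, SHEAR, amp / protocol.shear_speed, sign * protocol.shear_speed)
        if len(segments) > before:  # direction alternates only on real strokes
            sign = -sign

    # every motion is followed by a rest, including the last stroke; a
    # motionless protocol degenerates to a single rest
    _append(VERTICAL, REST, protocol.rest_duration, 0.0)

    return MotionSchedule(tuple(segments))


def sample_trajectory(schedule: MotionSchedule, rate: float) -> Trajectory:
    """Sample both stage trajectories at ``rate`` Hz (frame k at k/rate)."""
    if rate <= 0:
        raise ProtocolError("sampling rate must be positive")
    n = int(np.floor(schedule.total_duration * rate + 1e-9)) + 1
    time = np.arange(n) / rate
    vertical = np.atleast_1d(schedule.position_at(time, VERTICAL))
    horizontal = np.atleast_1d(schedule.position_at(time, HORIZONTAL))
    if schedule.segments:
        total = schedule.total_duration
        phases = tuple(phase_at(schedule, min(float(t), total))[0] for t in time)
    else:
        phases = tuple([REST] * n)
    return Trajectory(time, vertical, horizontal, phases)


def engineering_strain(displacement: float, initial_height: float) -> float:
    """Displacement over initial specimen height (dimensionless fraction)."""
    if initial_height <= 0:
        raise ProtocolError("initial_height must be positive")
    if displacement < 0:
        raise ProtocolError("displacement must be non-negative")
    return displacement / initial_height


def resample_force_to_frames(trace: ForceTrace, frame_rate: float) -> dict[str, np.ndarray]:
    """Average force samples over each frame interval of the video clock.

    Frame k spans [k/frame_rate, (k+1)/frame_rate); its value is the mean of
    the force samples whose timestamps fall in that interval.
    """
    if trace.time.size == 0:
        raise ProtocolError("cannot resample an empty trace")
    if trace.rate < frame_rate:
        raise ProtocolError("force rate must be at least the frame rate")
    idx = np.floor(trace.time * frame_rate + 1e-12).astype(int)
    n_frames = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_frames)
    out = {}
    for name in ("normal_force", "tangential_force"):
        sums = np.bincount(idx, weights=getattr(trace, name), minlength=n_frames)
        with np.errstate(invalid="ignore"):
            out[name] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out["time"] = np.arange(n_frames) / frame_rate
    out["counts"] = counts
    return out


def phase_at(schedule: MotionSchedule, t: float) -> tuple[str, Segment]:
    """Phase label and segment containing time ``t``.

    Segments are right-open: a boundary instant belongs to the later
    segment.  ``t == total_duration`` maps to the final segment.
    """
    if not schedule.segments:
        raise ProtocolError("empty schedule has no phases")
    if t < schedule.segments[0].t_start or t > schedule.total_duration:
        raise ProtocolError(f"t={t} outside schedule [0, {schedule.total_duration}]")
    for seg in schedule.segments:
        if seg.t_start <= t < seg.t_end:
            return seg.phase, seg
    last = schedule.segments[-1]
    return last.phase, last
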