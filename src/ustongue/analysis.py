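"""Interpretive quantities: friction phases, residual deformation, modulus.

Friction events are the velocity peaks locked to stroke boundaries: an
onset peak (static friction / elastic loading, extremum in the first half
of the stroke) and a stop peak of opposite polarity in the following rest.
The static phase of a stroke runs from stroke start to the onset peak, the
dynamic phase from the peak to stroke end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contour import ContourTable, fluctuation_map
from .piv import SurfaceTrace
from .protocol import MotionSchedule, REST, Segment

__all__ = [
    "FrictionEvent",
    "StrokePhases",
    "StressStrainCurve",
    "detect_friction_events",
    "classify_phases",
    "decay_time",
    "residual_deformation",
    "young_modulus",
]

ONSET = "onset_peak"
STOP = "stop_peak"


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class FrictionEvent:
    kind: str  # onset_peak | stop_peak
    time: float
    amplitude: float  # signed, px/frame
    duration: float  # width at half amplitude, s
    stroke_index: int
    stroke_start: float
    stroke_end: float
    decay_tau: float | None = None  # filled for onset peaks when fittable


@dataclass(frozen=True)
class StrokePhases:
    stroke_index: int
    static: tuple[float, float] | None  # [stroke start, onset-peak time]
    dynamic: tuple[float, float] | None  # (onset-peak time, stroke end]
    determined: bool


@dataclass(frozen=True)
class StressStrainCurve:
    """Monotone strain grid with matching stress values (kPa)."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        strain = np.asarray(self.strain, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        if strain.size != stress.size:
            raise AnalysisError("strain and stress must have equal lengths")
        if np.any(np.diff(strain) <= 0):
            raise AnalysisError("strain must be strictly increasing")
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress", stress)


def _rest_after(schedule: MotionSchedule, stroke: Segment) -> Segment | None:
    for seg in schedule.segments:
        if seg.phase == REST and abs(seg.t_start - stroke.t_end) < 1e-9:
            return seg
    return None


def _half_amplitude_width(times: np.ndarray, signal: np.ndarray, peak_idx: int) -> float:
    """Contiguous extent (s) around the peak where the signal stays above
    half the peak value (signal already oriented so the peak is positive)."""
    half = signal[peak_idx] / 2.0
    lo = peak_idx
    while lo > 0 and signal[lo - 1] >= half:
        lo -= 1
    hi = peak_idx
    while hi < signal.size - 1 and signal[hi + 1] >= half:
        hi += 1
    return float(times[hi] - times[lo])


def detect_friction_events(trace: SurfaceTrace, schedule: MotionSchedule) -> list[FrictionEvent]:
    """Locate onset/stop velocity peaks for every stroke covered by the trace.

    The noise floor is three times the trace standard deviation before the
    first stroke; peaks below it are not recorded.
    """
    times = np.asarray(trace.times, dtype=float)
    u = np.asarray(trace.u, dtype=float)
    if times.size != u.size or times.size == 0:
        raise AnalysisError("trace times and values must align and be non-empty")
    strokes = schedule.strokes()
    if not strokes:
        return []
    if times[0] > strokes[-1].t_end or times[-1] < strokes[0].t_start:
        raise AnalysisError("trace does not overlap the shear window of the schedule")

    first_start = min(s.t_start for s in strokes if s.t_start >= times[0] - 1e-9) if any(
        s.t_start >= times[0] - 1e-9 for s in strokes
    ) else strokes[0].t_start
    pre = u[times < first_start]
    floor = 3.0 * float(pre.std()) if pre.size >= 5 else 0.0

    events: list[FrictionEvent] = []
    for idx, stroke in enumerate(strokes):
        sg = math.copysign(1.0, stroke.velocity)
        onset_time = None

        mask = (times >= stroke.t_start) & (times <= stroke.t_start + stroke.duration / 2.0)
        if mask.any():
            w_t, w_u = times[mask], u[mask]
            i = int(np.argmax(sg * w_u))
            if sg * w_u[i] > max(floor, 1e-12):
                onset_time = float(w_t[i])
                events.append(
                    FrictionEvent(
                        ONSET,
                        onset_time,
                        float(w_u[i]),
                        _half_amplitude_width(w_t, sg * w_u, i),
                        idx,
                        stroke.t_start,
                        stroke.t_end,
                    )
                )

        rest = _rest_after(schedule, stroke)
        t_hi = rest.t_end if rest is not None else stroke.t_end + 1.5
        # right-open: a sample on the rest/stroke boundary belongs to the
        # next stroke, not to this stop window
        mask = (times > stroke.t_end) & (times < t_hi)
        if mask.any():
            w_t, w_u = times[mask], u[mask]
            i = int(np.argmax(-sg * w_u))
            if -sg * w_u[i] > max(floor, 1e-12):
                events.append(
                    FrictionEvent(
                        STOP,
                        float(w_t[i]),
                        float(w_u[i]),
                        _half_amplitude_width(w_t, -sg * w_u, i),
                        idx,
                        stroke.t_start,
                        stroke.t_end,
                    )
                )

    # fit decay constants for onset peaks now that events are in place
    fitted = []
    for ev in events:
        if ev.kind == ONSET:
            tau = decay_time(trace, ev)
            ev = FrictionEvent(
                ev.kind, ev.time, ev.amplitude, ev.duration, ev.stroke_index,
                ev.stroke_start, ev.stroke_end, decay_tau=tau,
            )
        fitted.append(ev)
    return fitted


def classify_phases(
    events: list[FrictionEvent],
    trace: SurfaceTrace,
    schedule: MotionSchedule,
) -> list[StrokePhases]:
    """Split each stroke into static ([start, onset peak]) and dynamic
    ((onset peak, end]) intervals; strokes without an onset event are
    flagged undetermined."""
    onsets = {ev.stroke_index: ev for ev in events if ev.kind == ONSET}
    times = np.asarray(trace.times, dtype=float)
    u = np.asarray(trace.u, dtype=float)
    out = []
    for idx, stroke in enumerate(schedule.strokes()):
        ev = onsets.get(idx)
        if ev is None:
            out.append(StrokePhases(idx, None, None, determined=False))
            continue
        # no post-peak velocity drop means the surface never slipped: the
        # whole stroke is static friction
        sg = math.copysign(1.0, ev.amplitude)
        # right-open: a pair starting exactly at stroke end samples the rest
        tail = (times > ev.time) & (times < stroke.t_end)
        slipped = tail.any() and float(np.min(sg * u[tail])) < 0.7 * sg * ev.amplitude
        if not slipped:
            out.append(
                StrokePhases(idx, static=(stroke.t_start, stroke.t_end),
                             dynamic=None, determined=True)
            )
        else:
            out.append(
                StrokePhases(
                    idx,
                    static=(stroke.t_start, ev.time),
                    dynamic=(ev.time, stroke.t_end),
                    determined=True,
                )
            )
    return out


def decay_time(trace: SurfaceTrace, event: FrictionEvent, min_samples: int = 10) -> float | None:
    """Exponential time constant of |u| after an onset peak.

    Least-squares fit of log|u| over the post-peak dynamic interval;
    non-decaying segments are flagged by returning None.
    """
    if event.kind != ONSET:
        raise AnalysisError("decay_time applies to onset peaks")
    times = np.asarray(trace.times, dtype=float)
    u = np.asarray(trace.u, dtype=float)
    mask = (times > event.time) & (times <= event.stroke_end)
    t, y = times[mask], np.abs(u[mask])
    if t.size < min_samples:
        return None
    keep = y > max(1e-9, 0.01 * y.max())
    t, y = t[keep], y[keep]
    if t.size < min_samples:
        return None
    slope, _ = np.polyfit(t, np.log(y), 1)
    if slope >= 0:
        return None
    return float(-1.0 / slope)


def residual_deformation(table: ContourTable, schedule: MotionSchedule) -> np.ndarray:
    """Per-stroke center-station ToF deviation averaged over the rest that
    follows each stroke (final frame for a stroke with no trailing rest)."""
    fluct = fluctuation_map(table)  # (stations, frames)
    center = fluct[fluct.shape[0] // 2]
    times = table.times
    out = []
    for stroke in schedule.strokes():
        rest = _rest_after(schedule, stroke)
        if rest is not None:
            mask = (times >= rest.t_start) & (times < rest.t_end)
        else:
            mask = times >= stroke.t_end
        if not mask.any():
            mask = np.zeros_like(times, dtype=bool)
            mask[-1] = True
        out.append(float(center[mask].mean()))
    return np.asarray(out)


def young_modulus(curve: StressStrainCurve, window: tuple[float, float] = (0.025, 0.05)) -> float:
    """OLS slope (kPa) of stress vs strain restricted to the linear window."""
    lo, hi = window
    mask = (curve.strain >= lo) & (curve.strain <= hi)
    if mask.sum() < 3:
        raise AnalysisError(f"need at least 3 points in the strain window [{lo}, {hi}]")
    slope, _ = np.polyfit(curve.strain[mask], curve.stress[mask], 1)
    return float(slope)
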