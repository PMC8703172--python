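"""Trace-level cell-cycle state segmentation and quiescence calls.

A :class:`ReporterTrace` (per-track Venus/Cherry time series) is binarized
per channel with moving-median smoothing, per-trace normalisation and
on/off hysteresis; the two boolean series compose into the four reporter
states::

    (off, off) = DN       double negative (S/G2/M, pre-onset)
    (on,  off) = V_ONLY   Venus only (early post-mitotic window)
    (on,  on ) = DP       double positive (the G0 decision window)
    (off, on ) = C_ONLY   Cherry only (G1)

State boundaries are refined by locating two level crossings on each edge
of the normalised signal and extrapolating the linear edge back to its
start, so an "on" boundary estimates the onset of the intensity rise and an
"off" boundary the start of the fall — the event-time convention of the
reporter kinetics — and the measured double-positive dwell is an unbiased
estimate of the simulated one regardless of ramp durations.  Derived
calls follow the printed rules: a DP phase prolonged beyond 14 h is
spontaneous G0 (strict inequality); a DP phase of more than 4 h that ends in
G1 entry is transient G0.  Cells still double positive at the movie end are
scored spontaneous if the observed dwell already exceeds the threshold and
are otherwise undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "ReporterTrace",
    "StateSegment",
    "CellCycleCall",
    "ClassifierConfig",
    "binarize_channel",
    "segment_states",
    "call_cell_cycle",
    "classify_trace",
    "cohort_signal_floor",
    "state_at",
]

STATES = ("DN", "V_ONLY", "DP", "C_ONLY")

#: transitions of the canonical reporter progression (plus self-loops);
#: anything else is flagged as an order violation
_CANONICAL = {
    ("DN", "V_ONLY"),
    ("V_ONLY", "DP"),
    ("DP", "C_ONLY"),
    ("C_ONLY", "DN"),
}


@dataclass
class ReporterTrace:
    """Uniformly sampled per-track reporter time series (hours, counts)."""

    times: np.ndarray
    venus: np.ndarray
    cherry: np.ndarray
    track_id: int = 0
    interpolated: Optional[np.ndarray] = None
    censored: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.venus = np.asarray(self.venus, dtype=float)
        self.cherry = np.asarray(self.cherry, dtype=float)
        if not (len(self.times) == len(self.venus) == len(self.cherry)):
            raise ValueError("trace arrays must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trace times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def end_h(self) -> float:
        return float(self.times[-1] + self.dt) if len(self.times) else 0.0


@dataclass(frozen=True)
class StateSegment:
    """A half-open classified interval ``[start_h, end_h)``."""

    state: str
    start_h: float
    end_h: float

    @property
    def duration_h(self) -> float:
        return self.end_h - self.start_h


@dataclass
class CellCycleCall:
    """Derived quiescence call for one trace.

    ``classifiable`` is False (with ``reason``) when the trace is too short,
    starts inside a DP phase, violates the canonical reporter order, or is
    censored inside a sub-threshold DP phase.
    """

    track_id: int = 0
    classifiable: bool = False
    reason: str = ""
    dp_duration_h: Optional[float] = None
    dp_start_h: Optional[float] = None
    spontaneous_g0: Optional[bool] = None
    transient_g0: Optional[bool] = None
    g1_entry_h: Optional[float] = None
    g1_entry_mid_h: Optional[float] = None
    g1_exit_h: Optional[float] = None
    censored_dp: bool = False
    trace_end_h: Optional[float] = None
    order_violations: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier knobs (hours and normalised-intensity fractions).

    ``theta_on``/``theta_off`` are hysteresis thresholds on the per-trace
    normalised signal (95th-percentile normalisation guards against
    cell-to-cell variation in absolute reporter intensity);
    ``signal_floor_venus``/``signal_floor_cherry`` put an absolute floor
    under the normalisation so reporter-silent traces do not amplify noise
    into spurious "on" calls (see :func:`cohort_signal_floor`).
    """

    smoothing_window_h: float = 1.5
    theta_on: float = 0.25
    theta_off: float = 0.15
    spontaneous_threshold_h: float = 14.0
    transient_threshold_h: float = 4.0
    sync_tolerance_h: float = 1.0
    min_state_dwell_h: float = 1.0
    boundary_level: float = 0.5
    signal_floor_venus: float = 0.0
    signal_floor_cherry: float = 0.0
    min_followup_h: float = 24.0

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_off < self.theta_on < 1.0):
            raise ValueError("need 0 < theta_off < theta_on < 1")
        for nm in ("spontaneous_threshold_h", "transient_threshold_h", "min_state_dwell_h"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")


def cohort_signal_floor(traces, fraction: float = 0.4) -> tuple[float, float]:
    """Per-channel absolute normalisation floor for a cohort of traces:
    ``fraction`` of the cohort 95th percentile of per-trace robust maxima.

    With a shared floor, a trace whose reporter never rises above a small
    fraction of a typical expressing cell stays "off" instead of being
    normalised up to full scale.
    """
    vmax = [float(np.percentile(t.venus, 95)) for t in traces if len(t) >= 3]
    cmax = [float(np.percentile(t.cherry, 95)) for t in traces if len(t) >= 3]
    fv = fraction * float(np.percentile(vmax, 95)) if vmax else 0.0
    fc = fraction * float(np.percentile(cmax, 95)) if cmax else 0.0
    return fv, fc


def _merge_short_runs(on: np.ndarray, min_samples: int) -> np.ndarray:
    """Iteratively absorb runs shorter than ``min_samples`` into their
    neighbours (shortest first; leftmost on ties)."""
    on = on.copy()
    while True:
        runs = _runs(on)
        if len(runs) <= 1:
            return on
        lengths = [b - a for a, b, _ in runs]
        k = int(np.argmin(lengths))
        if lengths[k] >= min_samples:
            return on
        a, b, v = runs[k]
        on[a:b] = not v
    return on


def _runs(on: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal constant runs as (start, stop, value) with stop exclusive."""
    if len(on) == 0:
        return []
    edges = np.flatnonzero(np.diff(on.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [len(on)]))
    return [(int(a), int(b), bool(on[a])) for a, b in zip(bounds[:-1], bounds[1:])]


def _refine_crossing(
    norm: np.ndarray, times: np.ndarray, idx: int, rising: bool, level: float
) -> float:
    """Interpolated time at which the normalised signal crosses ``level``
    nearest to the hysteresis switch at sample ``idx``."""
    n = len(norm)
    if rising:
        # idx is the first "on" sample; the level crossing may sit on either
        # side of it (theta_on is usually below the refinement level)
        if norm[idx] >= level:
            j = idx
            while j > 0 and norm[j - 1] >= level:
                j -= 1
        else:
            j = idx + 1
            while j < n and norm[j] < level:
                j += 1
            if j >= n:
                return float(times[idx])
        if j == 0:
            return float(times[idx])
        lo, hi = norm[j - 1], norm[j]
        frac = (level - lo) / (hi - lo) if hi != lo else 1.0
        return float(times[j - 1] + frac * (times[j] - times[j - 1]))
    # falling: idx is the first "off" sample; the downward crossing of the
    # level normally lies at or before it
    j = idx
    if norm[j] >= level:  # pathological: still above level, scan forward
        while j < n and norm[j] >= level:
            j += 1
        if j >= n:
            return float(times[idx])
    else:
        while j > 0 and norm[j - 1] < level:
            j -= 1
    if j == 0 or norm[j - 1] < level:
        return float(times[idx])
    lo, hi = norm[j - 1], norm[j]
    frac = (lo - level) / (lo - hi) if lo != hi else 0.0
    return float(times[j - 1] + frac * (times[j] - times[j - 1]))


class OnRun(NamedTuple):
    """One refined "on" interval of a binarized channel.

    ``t_on``/``t_off`` are the edge-extrapolated event times (onset of the
    rise, start of the fall; ``t_off`` is ``None`` while still on at trace
    end).  ``t_off_mid`` is the mid-level crossing of the falling edge — a
    lower-variance landmark used for comparing event times *between* cells,
    where the constant offset to the fall start cancels.
    """

    t_on: float
    t_off: Optional[float]
    t_off_mid: Optional[float] = None


def binarize_channel(
    values: np.ndarray,
    times: np.ndarray,
    config: ClassifierConfig,
    signal_floor: float = 0.0,
) -> tuple[np.ndarray, list[OnRun]]:
    """Binarize one channel with smoothing, normalisation and hysteresis.

    Returns the boolean on/off series and the list of refined
    :class:`OnRun` intervals.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(values) < 3:
        raise ValueError("trace shorter than 3 samples is unclassifiable")
    dt = times[1] - times[0]
    w = max(1, int(round(config.smoothing_window_h / dt)))
    if w % 2 == 0:
        w += 1
    smooth = median_filter(values, size=w, mode="nearest") if w > 1 else values
    denom = max(float(np.percentile(smooth, 95)), signal_floor, 1e-12)
    norm = smooth / denom

    on = np.zeros(len(norm), dtype=bool)
    state = norm[0] > config.theta_on
    for i, v in enumerate(norm):
        if state and v < config.theta_off:
            state = False
        elif not state and v > config.theta_on:
            state = True
        on[i] = state
    min_samples = max(1, int(round(config.min_state_dwell_h / dt)))
    on = _merge_short_runs(on, min_samples)

    events: list[OnRun] = []
    hi = config.boundary_level
    lo = config.theta_off
    for a, b, v in _runs(on):
        if not v:
            continue
        if a == 0:
            t_on = float(times[0])
        else:
            # extrapolate the rising edge back to its start (signal onset)
            t_lo = _refine_crossing(norm, times, a, True, lo)
            t_hi = _refine_crossing(norm, times, a, True, hi)
            t_on = t_lo - (t_hi - t_lo) * lo / (hi - lo) if t_hi > t_lo else t_lo
            t_on = max(t_on, float(times[0]))
        if b == len(on):
            t_off = t_off_mid = None
        else:
            # extrapolate the falling edge back to the start of the fall,
            # with levels relative to the run's own plateau: the per-trace
            # 95th-percentile normalisation varies from cell to cell, and
            # plateau-relative levels keep edge timing comparable between
            # cells
            run_vals = norm[a:b]
            plateau = (
                float(np.percentile(run_vals, 90)) if b - a >= 3 else float(run_vals.max())
            )
            plateau = max(plateau, 1e-9)
            t_hi = _refine_crossing(norm, times, b, False, hi * plateau)
            t_lo = _refine_crossing(norm, times, b, False, lo * plateau)
            t_off = t_hi - (t_lo - t_hi) * (1.0 - hi) / (hi - lo) if t_lo > t_hi else t_hi
            t_off = min(max(t_off, t_on + 1e-9), float(times[b]))
            t_off_mid = max(t_hi, t_on + 1e-9)
        events.append(OnRun(t_on, t_off, t_off_mid))
    return on, events


def _step_value(events, t: float) -> bool:
    for ev in events:
        if t >= ev.t_on and (ev.t_off is None or t < ev.t_off):
            return True
    return False


def segment_states(trace: ReporterTrace, config: ClassifierConfig | None = None):
    """Compose per-channel binarizations into contiguous state segments.

    Returns ``(segments, violations)`` where ``violations`` lists
    non-canonical transitions (flagged, never silently fixed).
    """
    config = config or ClassifierConfig()
    _, ev_v = binarize_channel(trace.venus, trace.times, config, config.signal_floor_venus)
    _, ev_c = binarize_channel(trace.cherry, trace.times, config, config.signal_floor_cherry)
    t0 = float(trace.times[0])
    t_end = trace.end_h
    breaks = {t0, t_end}
    for evs in (ev_v, ev_c):
        for ev in evs:
            if t0 < ev.t_on < t_end:
                breaks.add(ev.t_on)
            if ev.t_off is not None and t0 < ev.t_off < t_end:
                breaks.add(ev.t_off)
    bounds = sorted(breaks)
    segments: list[StateSegment] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (a + b)
        v = _step_value(ev_v, mid)
        c = _step_value(ev_c, mid)
        state = ("DN", "C_ONLY", "V_ONLY", "DP")[2 * v + c]
        if segments and segments[-1].state == state:
            segments[-1] = StateSegment(state, segments[-1].start_h, b)
        else:
            segments.append(StateSegment(state, a, b))
    violations = [
        f"{s1.state}->{s2.state}@{s2.start_h:.2f}h"
        for s1, s2 in zip(segments[:-1], segments[1:])
        if (s1.state, s2.state) not in _CANONICAL
    ]
    return segments, violations


def call_cell_cycle(
    segments: list[StateSegment],
    config: ClassifierConfig | None = None,
    censored_at: Optional[float] = None,
    track_id: int = 0,
    violations: Optional[list[str]] = None,
) -> CellCycleCall:
    """Derive the quiescence call from state segments.

    The scored DP phase is the first DP segment immediately preceded by a
    V_ONLY segment (the post-mitotic pattern); traces that start inside DP
    are left-censored and withheld.  Strict ``> threshold`` reading of the
    spontaneous rule; DP phases censored at the trace end are spontaneous
    only if the observed dwell already exceeds the threshold.
    """
    config = config or ClassifierConfig()
    call = CellCycleCall(track_id=track_id, order_violations=list(violations or []))
    if not segments:
        call.reason = "empty"
        return call
    end_h = segments[-1].end_h if censored_at is None else censored_at
    call.trace_end_h = end_h
    dp_idx = None
    for i, seg in enumerate(segments):
        if seg.state == "DP" and i > 0 and segments[i - 1].state == "V_ONLY":
            dp_idx = i
            break
    if dp_idx is None:
        if segments[0].state == "DP":
            call.reason = "left_censored_dp"
        elif any(s.state == "DP" for s in segments):
            call.reason = "dp_without_postmitotic_venus"
        else:
            call.reason = "no_dp_phase"
        return call
    dp = segments[dp_idx]
    call.dp_duration_h = dp.duration_h
    call.dp_start_h = dp.start_h
    call.trace_end_h = end_h
    call.censored_dp = dp.end_h >= end_h - 1e-9
    followed_by_g1 = (
        dp_idx + 1 < len(segments) and segments[dp_idx + 1].state == "C_ONLY"
    )
    if call.censored_dp:
        if dp.duration_h > config.spontaneous_threshold_h:
            call.classifiable = True
            call.spontaneous_g0 = True
            call.transient_g0 = False
        else:
            call.reason = "censored_dp_below_threshold"
        return call
    if not followed_by_g1:
        # DP ended but not into G1 (non-canonical, e.g. both reporters lost)
        call.reason = "dp_end_not_g1"
        return call
    call.classifiable = True
    call.spontaneous_g0 = dp.duration_h > config.spontaneous_threshold_h
    call.g1_entry_h = dp.end_h
    call.transient_g0 = (
        not call.spontaneous_g0 and dp.duration_h > config.transient_threshold_h
    )
    g1 = segments[dp_idx + 1]
    if g1.end_h < end_h - 1e-9:
        call.g1_exit_h = g1.end_h
    return call


def classify_trace(
    trace: ReporterTrace, config: ClassifierConfig | None = None
) -> CellCycleCall:
    """Segment and call one trace; traces shorter than 3 samples are
    rejected as unclassifiable (logged in the call reason, not fatal).

    In addition to the call, the mid-level crossing of the Venus fall that
    defines G1 entry is recorded (``g1_entry_mid_h``): between-cell timing
    comparisons use it because the constant mid-to-start offset cancels in
    differences while its noise is several-fold smaller than that of the
    extrapolated fall start.
    """
    config = config or ClassifierConfig()
    if len(trace) < 3:
        return CellCycleCall(track_id=trace.track_id, reason="too_short")
    segments, violations = segment_states(trace, config)
    call = call_cell_cycle(
        segments, config, censored_at=trace.end_h, track_id=trace.track_id,
        violations=violations,
    )
    if call.g1_entry_h is not None:
        _, ev_v = binarize_channel(
            trace.venus, trace.times, config, config.signal_floor_venus
        )
        for ev in ev_v:
            if ev.t_off is not None and abs(ev.t_off - call.g1_entry_h) < 1e-6:
                call.g1_entry_mid_h = ev.t_off_mid
                break
    return call


def state_at(segments: list[StateSegment], t_h: float) -> Optional[str]:
    """State at time ``t_h`` (half-open segments; None outside the span)."""
    for seg in segments:
        if seg.start_h <= t_h < seg.end_h:
            return seg.state
    if segments and abs(t_h - segments[-1].end_h) < 1e-9:
        return segments[-1].state
    return None
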