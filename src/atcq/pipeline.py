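"""End-to-end orchestration: movie -> detections -> tracks -> traces ->
calls -> daughter pairs -> population summary.

Every stage consumes and produces plain tables, so stages can be rerun
independently; the full analysis of one stack is a pure function of the
pixels and the parameters.  ``simulate_and_analyze`` runs a profile through
the whole loop (simulate, render, analyse) in independent small fields, the
way a microfluidic cell-hotel experiment records many chambers in parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import (
    CellCycleCall,
    ClassifierConfig,
    classify_trace,
    cohort_signal_floor,
    segment_states,
    state_at,
)
from .lineage import DaughterPairCall, PopulationSummary, classify_daughter_pair, summarize_population
from .profiles import KineticProfile, get_profile
from .render import render_movie
from .segmentation import SegmentationParams, segment_movie
from .simulate import MovieSpec, simulate_population, trace_arrays_from_record
from .tracking import Track, TrackingParams, extract_trace, track_detections
from .classification import ReporterTrace

__all__ = [
    "PipelineResult",
    "analyze_stack",
    "classify_tracks",
    "simulate_and_analyze",
    "snapshot_state_fractions",
]


@dataclass
class PipelineResult:
    """Bundle of all stage outputs for one movie (or pooled fields)."""

    detections: pd.DataFrame
    tracks: list[Track]
    traces: list[ReporterTrace]
    calls: list[CellCycleCall]
    pairs: list[DaughterPairCall]
    summary: PopulationSummary
    observation_spans: dict[int, tuple[float, float]] = field(default_factory=dict)
    division_times_h: list[float] = field(default_factory=list)
    n_short_tracks: int = 0


def classify_tracks(
    tracks: list[Track],
    frame_interval_h: float,
    duration_h: float,
    clf: ClassifierConfig | None = None,
    min_track_len: int = 6,
) -> PipelineResult:
    """Classification + pair scoring for already-linked tracks."""
    clf = clf or ClassifierConfig()
    usable = [t for t in tracks if len(t) >= min_track_len]
    n_short = len(tracks) - len(usable)
    traces = [extract_trace(t, frame_interval_h) for t in usable]
    if clf.signal_floor_venus == 0.0 and clf.signal_floor_cherry == 0.0 and traces:
        fv, fc = cohort_signal_floor(traces)
        clf = ClassifierConfig(
            **{
                **{k: getattr(clf, k) for k in clf.__dataclass_fields__},
                "signal_floor_venus": fv,
                "signal_floor_cherry": fc,
            }
        )
    calls = {tr.track_id: classify_trace(tr, clf) for tr in traces}
    by_id = {t.track_id: t for t in tracks}

    spans: dict[int, tuple[float, float]] = {}
    division_times: list[float] = []
    pairs: list[DaughterPairCall] = []
    for t in tracks:
        if len(t) == 0:
            continue
        spans[t.track_id] = (t.start_frame * frame_interval_h, duration_h)
        if len(t.child_track_ids) == 2:
            kids = [by_id[c] for c in t.child_track_ids if c in by_id]
            if len(kids) != 2:
                continue
            div_t = min(k.start_frame for k in kids) * frame_interval_h
            division_times.append(div_t)
            c1 = calls.get(kids[0].track_id, CellCycleCall(track_id=kids[0].track_id, reason="too_short"))
            c2 = calls.get(kids[1].track_id, CellCycleCall(track_id=kids[1].track_id, reason="too_short"))
            if duration_h - div_t < clf.min_followup_h:
                # not enough potential observation to resolve either fate
                pairs.append(
                    DaughterPairCall(t.track_id, "UNDETERMINED", div_t)
                )
            else:
                pairs.append(
                    classify_daughter_pair(
                        c1, c2, clf, parent_track_id=t.track_id,
                        division_time_h=div_t, observation_end_h=duration_h,
                    )
                )
    call_list = list(calls.values())
    summary = summarize_population(
        call_list,
        pairs,
        clf,
        observation_spans=spans,
        division_times=division_times,
    )
    return PipelineResult(
        detections=pd.DataFrame(),
        tracks=tracks,
        traces=traces,
        calls=call_list,
        pairs=pairs,
        summary=summary,
        observation_spans=spans,
        division_times_h=division_times,
        n_short_tracks=n_short,
    )


def analyze_stack(
    stack: np.ndarray,
    frame_interval_h: float,
    seg_params: SegmentationParams | None = None,
    trk_params: TrackingParams | None = None,
    clf: ClassifierConfig | None = None,
) -> PipelineResult:
    """Full pipeline on one ``(T, 2, H, W)`` stack."""
    seg_params = seg_params or SegmentationParams()
    trk_params = trk_params or TrackingParams(psf_sigma=seg_params.psf_sigma)
    duration_h = stack.shape[0] * frame_interval_h
    detections = segment_movie(stack, seg_params)
    tracks = track_detections(detections, trk_params)
    res = classify_tracks(
        tracks, frame_interval_h, duration_h, clf, min_track_len=trk_params.min_track_len
    )
    res.detections = detections
    return res


def _pool_results(parts: list[PipelineResult]) -> PipelineResult:
    """Pool stage outputs of independent fields, re-keying track ids."""
    calls: list[CellCycleCall] = []
    pairs: list[DaughterPairCall] = []
    spans: dict[int, tuple[float, float]] = {}
    division_times: list[float] = []
    tracks: list[Track] = []
    traces: list[ReporterTrace] = []
    offset = 0
    n_short = 0
    for part in parts:
        ids = [t.track_id for t in part.tracks] + list(part.observation_spans)
        width = (max(ids) + 1) if ids else 0
        for c in part.calls:
            c.track_id += offset
            calls.append(c)
        for p in part.pairs:
            p.parent_track_id += offset
            pairs.append(p)
        for tid, span in part.observation_spans.items():
            spans[tid + offset] = span
        division_times.extend(part.division_times_h)
        tracks.extend(part.tracks)
        traces.extend(part.traces)
        n_short += part.n_short_tracks
        offset += width
    summary = summarize_population(
        calls, pairs, ClassifierConfig(), observation_spans=spans,
        division_times=division_times,
    )
    return PipelineResult(
        detections=pd.DataFrame(),
        tracks=tracks,
        traces=traces,
        calls=calls,
        pairs=pairs,
        summary=summary,
        observation_spans=spans,
        division_times_h=division_times,
        n_short_tracks=n_short,
    )


def simulate_and_analyze(
    profile: KineticProfile | str,
    n_founders: int,
    seed: int,
    spec: MovieSpec | None = None,
    founders_per_field: int = 10,
    seg_params: SegmentationParams | None = None,
    trk_params: TrackingParams | None = None,
    clf: ClassifierConfig | None = None,
) -> PipelineResult:
    """Simulate ``n_founders`` cells in independent fields, render each field
    with noise, and run the blind pipeline; results are pooled.

    The pipeline never sees the ground truth: it works purely on the
    rendered pixels.
    """
    if isinstance(profile, str):
        profile = get_profile(profile)
    spec = spec or MovieSpec()
    parts: list[PipelineResult] = []
    remaining = n_founders
    k = 0
    while remaining > 0:
        nf = min(founders_per_field, remaining)
        remaining -= nf
        field_seed = (seed * 10_000 + k) % (2**31 - 1)
        k += 1
        lineage = simulate_population(profile, nf, spec, seed=field_seed)
        stack, _truth = render_movie(lineage, spec, seed=field_seed + 1, profile=profile)
        parts.append(
            analyze_stack(stack, spec.frame_interval_h, seg_params, trk_params, clf)
        )
    if not parts:
        return _pool_results([])
    return _pool_results(parts)


def snapshot_state_fractions(
    profile: KineticProfile | str,
    n_cells: int,
    seed: int,
    spec: MovieSpec | None = None,
    noise_sigma: float = 0.03,
    basal: float = 0.03,
    clf: ClassifierConfig | None = None,
) -> dict[str, float]:
    """Percent of cells in each reporter state at the final frame.

    Emulates the flow-cytometry style endpoint readout: per-cell traces are
    generated (in intensity-fraction units with basal signal and noise),
    classified, and the state at the last sampled time is tallied over all
    cells alive at the end of the observation window.
    """
    if isinstance(profile, str):
        profile = get_profile(profile)
    spec = spec or MovieSpec()
    rng = np.random.default_rng(seed)
    lineage = simulate_population(profile, n_cells, spec, seed=seed, with_positions=False)
    final_frame = spec.n_frames - 1
    final_t = final_frame * spec.frame_interval_h
    traces = []
    for rec in lineage.records:
        if rec.n_frames_alive == 0 or rec.frames()[-1] != final_frame:
            continue  # not alive at the end
        t, v, c = trace_arrays_from_record(
            rec, profile, spec, noise_sigma=noise_sigma, basal=basal, rng=rng
        )
        traces.append(ReporterTrace(times=t, venus=v, cherry=c, track_id=rec.cell_id))
    clf = clf or ClassifierConfig()
    if clf.signal_floor_venus == 0.0 and traces:
        fv, fc = cohort_signal_floor(traces)
        clf = ClassifierConfig(
            **{
                **{k: getattr(clf, k) for k in clf.__dataclass_fields__},
                "signal_floor_venus": fv,
                "signal_floor_cherry": fc,
            }
        )
    counts = {"DN": 0, "V_ONLY": 0, "DP": 0, "C_ONLY": 0, "unclassified": 0}
    for tr in traces:
        if len(tr) < 3:
            counts["unclassified"] += 1
            continue
        segments, _ = segment_states(tr, clf)
        st = state_at(segments, final_t)
        counts[st if st in counts else "unclassified"] += 1
    total = sum(counts.values())
    return {k: (100.0 * v / total if total else float("nan")) for k, v in counts.items()}
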