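"""Linking, gap closing, division detection, trace extraction."""

import numpy as np
import pandas as pd
import pytest

import atcq
from atcq.tracking import (
    Track,
    TrackingParams,
    extract_trace,
    link_detections,
    track_detections,
)
from atcq.validation import (
    division_recovery,
    link_accuracy,
    match_tracks_to_truth,
)


def _det_table(rows):
    """rows: (frame, x, y) or (frame, x, y, venus, cherry)."""
    full = [(r + (0.0, 0.0))[:5] for r in rows]
    df = pd.DataFrame(full, columns=["frame_index", "x", "y", "mean_venus", "mean_cherry"])
    df["label"] = df.groupby("frame_index").cumcount() + 1
    df["area"] = 10
    df["total_venus"] = 0.0
    df["total_cherry"] = 0.0
    return df


def test_single_static_cell_one_track():
    det = _det_table([(f, 10.0, 10.0) for f in range(10)])
    tracks = link_detections(det)
    assert len(tracks) == 1
    assert len(tracks[0]) == 10


def test_no_swap_beyond_max_displacement():
    """Two cells that would have to jump farther than max_displacement to
    swap stay on separate tracks."""
    rows = []
    for f in range(6):
        rows.append((f, 10.0, 10.0))
        rows.append((f, 40.0, 10.0))
    tracks = link_detections(_det_table(rows), TrackingParams(max_displacement=5.0))
    assert len(tracks) == 2
    for t in tracks:
        xs = set(np.round(t.xs, 1))
        assert len(xs) == 1  # never jumps between the two positions


def test_gap_closing_joins_interrupted_track():
    rows = [(f, 20.0, 20.0) for f in range(5)] + [(f, 20.5, 20.0) for f in range(7, 12)]
    tracks = link_detections(_det_table(rows), TrackingParams(max_gap=4))
    assert len(tracks) == 1
    trace = extract_trace(tracks[0], 0.5)
    assert trace.interpolated.sum() == 2  # frames 5 and 6 filled in


def test_division_fixture_one_parent_two_children():
    """A blob vanishing at frame 4 with two blobs appearing at frame 5
    flanking its position becomes one parent with exactly two children."""
    rows = [(f, 30.0, 30.0) for f in range(5)]
    for f in range(5, 10):
        rows.append((f, 25.0, 30.0))
        rows.append((f, 35.0, 30.0))
    tracks = track_detections(_det_table(rows))
    parents = [t for t in tracks if len(t.child_track_ids) == 2]
    assert len(parents) == 1
    kids = [t for t in tracks if t.parent_track_id == parents[0].track_id]
    assert len(kids) == 2
    assert all(k.start_frame == 5 for k in kids)


def test_track_ending_at_movie_end_has_no_children():
    rows = [(f, 10.0, 10.0) for f in range(10)]
    tracks = track_detections(_det_table(rows))
    assert tracks[0].child_track_ids == []


def test_three_candidate_daughters_only_best_two_adopted():
    rows = [(f, 30.0, 30.0) for f in range(5)]
    for f in range(5, 10):
        rows.append((f, 27.0, 30.0))
        rows.append((f, 33.0, 30.0))
        rows.append((f, 30.0, 36.5))  # third, farther appearance
    tracks = track_detections(_det_table(rows))
    parents = [t for t in tracks if t.child_track_ids]
    assert len(parents) == 1
    assert len(parents[0].child_track_ids) == 2
    kids = {t.track_id for t in tracks if t.parent_track_id is not None}
    roots = [t for t in tracks if t.parent_track_id is None and t.start_frame == 5]
    assert len(roots) == 1  # the third appearance starts its own root
    assert abs(roots[0].ys[0] - 36.5) < 1e-9


def test_every_detection_in_at_most_one_track(hotel_analysis):
    res, _ = hotel_analysis
    seen = set()
    for t in res.tracks:
        for k in range(len(t)):
            key = (t.frames[k], round(t.xs[k], 4), round(t.ys[k], 4))
            assert key not in seen
            seen.add(key)


def test_lineage_acyclic_and_two_children(hotel_analysis):
    res, _ = hotel_analysis
    by_id = {t.track_id: t for t in res.tracks}
    for t in res.tracks:
        assert len(t.child_track_ids) in (0, 2)
        # walk to root, must terminate
        steps, cur = 0, t
        while cur.parent_track_id is not None:
            cur = by_id[cur.parent_track_id]
            steps += 1
            assert steps < 1000
        for c in t.child_track_ids:
            assert by_id[c].start_frame > t.end_frame - TrackingParams().max_gap


def test_link_accuracy_on_hotel_field(hotel_analysis):
    """>= 99% of frame-to-frame links join the same ground-truth cell."""
    res, matched = hotel_analysis
    assert link_accuracy(res.tracks, matched) >= 0.99


def test_division_recovery_on_hotel_field(hotel_analysis, hotel_field):
    """>= 95% of ground-truth divisions recovered with correct parent and
    both daughters."""
    lineage, _, _ = hotel_field
    res, matched = hotel_analysis
    t2c = match_tracks_to_truth(res.tracks, matched)
    assert division_recovery(res.tracks, t2c, lineage.cells_dataframe()) >= 0.95


def test_trace_extraction_monotone_for_g0_cell(hotel_profile):
    """A rendered noiseless G0 cell yields monotone non-decreasing (then
    plateau) Venus and Cherry traces."""
    spec = atcq.MovieSpec(
        duration_h=30.0, width=64, height=64, shot_noise=False, read_noise_sigma=0.0
    )
    prof = hotel_profile.with_overrides(
        motility_sigma=0.0, founder_spread_h=0.0, p_spontaneous_g0=1.0,
        pair_fate_probs=(1.0, 0.0, 0.0),
    )
    lineage = atcq.simulate_population(prof, 1, spec, seed=21)
    stack, _ = atcq.render_movie(lineage, spec, seed=22, profile=prof)
    det = atcq.segment_movie(stack)
    tracks = link_detections(det)
    assert len(tracks) == 1
    trace = extract_trace(tracks[0], spec.frame_interval_h)
    for series in (trace.venus, trace.cherry):
        # allow tiny numerical wiggle from mask rounding
        assert np.all(np.diff(series) > -0.02 * series.max())


def test_trace_length_one_no_interpolation():
    t = Track(track_id=0)
    t.append(3, 1.0, 2.0, 5.0, 6.0)
    trace = extract_trace(t, 0.5)
    assert len(trace) == 1
    assert trace.times[0] == 1.5
    assert not trace.interpolated.any()


def test_gap_interpolation_is_neighbour_mean():
    t = Track(track_id=0)
    t.append(0, 0.0, 0.0, 10.0, 2.0)
    t.append(2, 0.0, 0.0, 20.0, 4.0)
    trace = extract_trace(t, 0.5)
    assert trace.interpolated.tolist() == [False, True, False]
    assert trace.venus[1] == pytest.approx(15.0)
    assert trace.cherry[1] == pytest.approx(3.0)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        TrackingParams(max_displacement=-1)
    with pytest.raises(ValueError):
        TrackingParams(method="psychic")
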