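"""Binarization, state segmentation and quiescence calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import atcq
from atcq.classification import (
    ClassifierConfig,
    ReporterTrace,
    StateSegment,
    binarize_channel,
    call_cell_cycle,
    classify_trace,
    cohort_signal_floor,
    segment_states,
    state_at,
)
from tests.conftest import noiseless_trace

CFG = ClassifierConfig()


def _times(n, dt=0.5):
    return np.arange(n) * dt


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def test_all_zero_series_stays_off():
    t = _times(40)
    on, events = binarize_channel(np.zeros(40), t, CFG)
    assert not on.any()
    assert events == []


def test_clean_step_switches_within_one_frame():
    t = _times(60)
    values = (t >= 10.0).astype(float)
    on, events = binarize_channel(values, t, CFG)
    assert len(events) == 1
    assert abs(events[0].t_on - 10.0) <= 0.5 + 1e-9
    assert events[0].t_off is None


def test_ramp_up_down_single_run_with_fall_timing():
    """A noiseless 4 h rise / 3 h fall pulse gives one on-run whose off
    boundary lands at the start of the fall (within one frame)."""
    dt = 0.5
    t = _times(80, dt)
    rise_t0, plateau_end = 5.0, 20.0
    fall = 3.0
    values = np.clip((t - rise_t0) / 4.0, 0, 1) * np.clip(
        (plateau_end + fall - t) / fall, 0, 1
    )
    values = np.minimum(values, 1.0)
    on, events = binarize_channel(values, t, CFG)
    assert len(events) == 1
    assert abs(events[0].t_on - rise_t0) <= 0.5 + 1e-9
    assert plateau_end - 0.5 <= events[0].t_off <= plateau_end + fall
    # the mid-level crossing sits inside the fall, after its start
    assert events[0].t_off <= events[0].t_off_mid <= plateau_end + fall


def test_short_trace_rejected():
    with pytest.raises(ValueError):
        binarize_channel(np.zeros(2), _times(2), CFG)
    call = classify_trace(
        ReporterTrace(times=_times(2), venus=np.zeros(2), cherry=np.zeros(2))
    )
    assert not call.classifiable
    assert call.reason == "too_short"


def test_signal_floor_suppresses_silent_noise():
    """A reporter-silent trace (basal + noise) must not be normalised up
    into spurious 'on' calls when a cohort floor is supplied."""
    rng = np.random.default_rng(0)
    t = _times(144)
    silent = 0.03 + rng.normal(0, 0.03, size=144)
    bright = np.clip((t - 10) / 3.0, 0, 1) + rng.normal(0, 0.03, size=144)
    traces = [
        ReporterTrace(times=t, venus=np.clip(v, 0, None), cherry=np.zeros(144))
        for v in (silent, bright)
    ]
    fv, _ = cohort_signal_floor(traces)
    on_silent, _ = binarize_channel(traces[0].venus, t, CFG, signal_floor=fv)
    on_bright, _ = binarize_channel(traces[1].venus, t, CFG, signal_floor=fv)
    assert not on_silent.any()
    assert on_bright.any()


# ---------------------------------------------------------------------------
# state segmentation
# ---------------------------------------------------------------------------


def test_all_zero_trace_is_single_dn_segment():
    tr = ReporterTrace(times=_times(30), venus=np.zeros(30), cherry=np.zeros(30))
    segments, violations = segment_states(tr, CFG)
    assert [s.state for s in segments] == ["DN"]
    assert violations == []
    assert segments[0].start_h == 0.0
    assert segments[0].end_h == pytest.approx(tr.end_h)


def test_cycler_trace_segments_match_generator_events(hotel_profile, movie_spec):
    """Noiseless generator traces segment into DN-V_ONLY-DP-C_ONLY(-DN)
    with boundaries within one frame of the simulated event times."""
    lin = atcq.simulate_population(hotel_profile, 40, movie_spec, seed=8, with_positions=False)
    checked = 0
    for rec in lin.records:
        if rec.venus_off_h is None or rec.cherry_off_h is None or rec.birth_h < 0:
            continue
        tr = noiseless_trace(rec, hotel_profile, movie_spec)
        segments, violations = segment_states(tr, CFG)
        assert violations == []
        states = [s.state for s in segments]
        assert states[:4] == ["DN", "V_ONLY", "DP", "C_ONLY"]
        dp = segments[2]
        assert dp.start_h == pytest.approx(rec.cherry_on_h, abs=0.5)
        assert dp.end_h == pytest.approx(rec.venus_off_h, abs=0.5)
        checked += 1
    assert checked >= 5


def test_starved_trace_has_terminal_dp(hotel_profile, movie_spec):
    """Serum-starvation style trace (both reporters rise, never fall) ends
    in a DP segment extending to the trace end."""
    prof = hotel_profile.with_overrides(
        p_spontaneous_g0=1.0, pair_fate_probs=(1.0, 0.0, 0.0), founder_spread_h=0.0
    )
    lin = atcq.simulate_population(prof, 3, movie_spec, seed=9, with_positions=False)
    for rec in lin.records:
        tr = noiseless_trace(rec, prof, movie_spec)
        segments, _ = segment_states(tr, CFG)
        assert segments[-1].state == "DP"
        assert segments[-1].end_h == pytest.approx(tr.end_h)


# ---------------------------------------------------------------------------
# calls
# ---------------------------------------------------------------------------


def _segments(*spans):
    return [StateSegment(state, a, b) for state, a, b in spans]


@pytest.mark.parametrize(
    "dp_len, expect_spont, expect_transient",
    [(15.0, True, False), (14.0, False, True), (6.0, False, True), (3.0, False, False)],
)
def test_spontaneous_rule_is_strict(dp_len, expect_spont, expect_transient):
    segs = _segments(
        ("DN", 0, 2), ("V_ONLY", 2, 4), ("DP", 4, 4 + dp_len),
        ("C_ONLY", 4 + dp_len, 4 + dp_len + 8), ("DN", 4 + dp_len + 8, 40),
    )
    call = call_cell_cycle(segs, CFG, censored_at=40.0)
    assert call.classifiable
    assert call.spontaneous_g0 is expect_spont
    assert call.transient_g0 is expect_transient
    assert call.g1_entry_h == pytest.approx(4 + dp_len)


def test_censored_dp_below_threshold_is_undetermined():
    segs = _segments(("DN", 0, 2), ("V_ONLY", 2, 4), ("DP", 4, 14))
    call = call_cell_cycle(segs, CFG, censored_at=14.0)
    assert not call.classifiable
    assert call.reason == "censored_dp_below_threshold"
    assert call.censored_dp


def test_censored_dp_beyond_threshold_is_spontaneous():
    segs = _segments(("DN", 0, 2), ("V_ONLY", 2, 4), ("DP", 4, 30))
    call = call_cell_cycle(segs, CFG, censored_at=30.0)
    assert call.classifiable
    assert call.spontaneous_g0
    assert call.censored_dp
    assert call.g1_entry_h is None


def test_left_censored_dp_withheld():
    segs = _segments(("DP", 0, 20), ("C_ONLY", 20, 30))
    call = call_cell_cycle(segs, CFG, censored_at=30.0)
    assert not call.classifiable
    assert call.reason == "left_censored_dp"


def test_oracle_equivalence_noiseless(hotel_profile, movie_spec):
    """Classification of noiseless generator traces reproduces the
    generator fate labels for 100% of eligible cells."""
    lin = atcq.simulate_population(hotel_profile, 60, movie_spec, seed=10, with_positions=False)
    tot = agree = 0
    for rec in lin.records:
        if rec.dp_dwell_h is None or rec.n_frames_alive < 3:
            continue
        if movie_spec.duration_h - rec.birth_h < CFG.min_followup_h:
            continue
        call = classify_trace(noiseless_trace(rec, hotel_profile, movie_spec), CFG)
        if not call.classifiable:
            continue
        tot += 1
        agree += int(bool(call.spontaneous_g0) == (rec.dp_dwell_h > 14))
    assert tot >= 100
    assert agree == tot


@given(thresholds=st.lists(st.floats(5.0, 30.0), min_size=2, max_size=6))
@settings(max_examples=25, deadline=None)
def test_spontaneous_count_monotone_in_threshold(thresholds):
    """Raising the spontaneous threshold never increases the number of
    spontaneous-G0 calls on a fixed trace set."""
    rng = np.random.default_rng(1234)
    t = _times(144)
    traces = []
    for _ in range(12):
        on_t = rng.uniform(2, 6)
        dwell = rng.uniform(2, 30)
        venus = np.clip((t - on_t) / 3.0, 0, 1) * np.clip((on_t + 4 + dwell - t) / 3.0, 0, 1)
        cherry = np.clip((t - on_t - 4) / 3.0, 0, 1)
        venus = np.minimum(venus, 1)
        traces.append(
            ReporterTrace(times=t, venus=venus + rng.normal(0, 0.01, 144),
                          cherry=cherry + rng.normal(0, 0.01, 144))
        )
    counts = []
    for thr in sorted(thresholds):
        cfg = ClassifierConfig(spontaneous_threshold_h=thr)
        n = sum(
            1 for tr in traces
            if (c := classify_trace(tr, cfg)).classifiable and c.spontaneous_g0
        )
        counts.append(n)
    assert counts == sorted(counts, reverse=True)


def test_classification_deterministic(hotel_profile, movie_spec):
    lin = atcq.simulate_population(hotel_profile, 5, movie_spec, seed=13, with_positions=False)
    rec = next(r for r in lin.records if r.dp_dwell_h is not None)
    tr = noiseless_trace(rec, hotel_profile, movie_spec)
    c1, c2 = classify_trace(tr, CFG), classify_trace(tr, CFG)
    assert c1 == c2


def test_state_at_lookup():
    segs = _segments(("DN", 0, 2), ("DP", 2, 10))
    assert state_at(segs, 1.0) == "DN"
    assert state_at(segs, 2.0) == "DP"
    assert state_at(segs, 10.0) == "DP"
    assert state_at(segs, 11.0) is None
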