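"""Daughter-pair scoring, population summaries, Mann-Whitney comparisons."""

import numpy as np
import pytest
from scipy import stats as sps

import atcq
from atcq.classification import CellCycleCall, ClassifierConfig
from atcq.lineage import (
    DaughterPairCall,
    asynchrony_delta,
    classify_daughter_pair,
    compare_duration_distributions,
    division_timing_profile,
    summarize_population,
)

CFG = ClassifierConfig()


def _call(g1_entry=None, spont=False, dwell=5.0, censored=False, dp_start=4.0,
          trace_end=72.0, classifiable=True):
    return CellCycleCall(
        track_id=0,
        classifiable=classifiable,
        dp_duration_h=dwell,
        dp_start_h=dp_start,
        spontaneous_g0=spont,
        transient_g0=(not spont and g1_entry is not None and dwell > 4),
        g1_entry_h=g1_entry,
        censored_dp=censored,
        trace_end_h=trace_end,
    )


def test_one_entered_one_spontaneous_is_async():
    pc = classify_daughter_pair(_call(g1_entry=6.0), _call(spont=True, dwell=30, censored=True), CFG)
    assert pc.category == "ASYNC"
    assert asynchrony_delta(pc) is None  # right-censored delta
    assert pc.censored_delta


def test_both_entered_within_tolerance_is_sync_g1():
    pc = classify_daughter_pair(_call(g1_entry=8.0), _call(g1_entry=8.4), CFG)
    assert pc.category == "SYNC_G1"
    assert pc.delta_g1_entry_h == pytest.approx(0.4)


def test_both_entered_beyond_tolerance_is_async_with_delta():
    pc = classify_daughter_pair(_call(g1_entry=10.0), _call(g1_entry=13.0), CFG)
    assert pc.category == "ASYNC"
    assert asynchrony_delta(pc) == pytest.approx(3.0)


def test_both_spontaneous_is_sync_g0():
    pc = classify_daughter_pair(
        _call(spont=True, dwell=20, censored=True), _call(spont=True, dwell=25, censored=True), CFG
    )
    assert pc.category == "SYNC_G0"
    assert pc.delta_g1_entry_h is None


def test_unclassifiable_daughter_gives_undetermined():
    pc = classify_daughter_pair(_call(g1_entry=6.0), _call(classifiable=False), CFG)
    assert pc.category == "UNDETERMINED"


def test_track_loss_mid_dp_is_not_asynchrony():
    """A sibling censored in DP because its track was lost mid-movie must
    not be scored as a G0-resident partner."""
    lost = _call(dwell=6.0, censored=True, trace_end=30.0, dp_start=4.0)
    lost.classifiable = False
    pc = classify_daughter_pair(_call(g1_entry=12.0), lost, CFG, observation_end_h=72.0)
    assert pc.category == "UNDETERMINED"
    # same sibling observed through the movie end: genuine asynchrony
    held = _call(dwell=66.0, censored=True, trace_end=72.0, dp_start=4.0)
    held.classifiable = False
    pc2 = classify_daughter_pair(_call(g1_entry=12.0), held, CFG, observation_end_h=72.0)
    assert pc2.category == "ASYNC"


def test_summary_arithmetic():
    calls = [_call(g1_entry=10.0, dwell=6.0) for _ in range(7)]
    calls += [_call(spont=True, dwell=20.0, censored=True) for _ in range(3)]
    for i, c in enumerate(calls):
        c.track_id = i
    s = summarize_population(calls, [], CFG)
    assert s.n_classifiable_postmitotic == 10
    assert s.percent_spontaneous_g0 == pytest.approx(30.0)
    assert s.percent_transient_g0 == pytest.approx(70.0)


def test_all_sync_g1_pairs_zero_async_percent():
    pairs = [DaughterPairCall(i, "SYNC_G1", 10.0, 0.2) for i in range(5)]
    s = summarize_population([], pairs, CFG)
    assert s.percent_async_pairs == 0.0
    assert sum(s.pair_counts.values()) == 5


def test_pair_category_conservation(hotel_analysis):
    res, _ = hotel_analysis
    s = res.summary
    assert sum(s.pair_counts.values()) == len(res.pairs)
    assert all(v >= 0 for v in s.pair_counts.values())


def test_empty_summary_sentinel():
    s = summarize_population([], [], CFG)
    assert s.n_tracked == 0
    assert np.isnan(s.percent_spontaneous_g0)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def test_mann_whitney_exact_small_example():
    """{1,2} vs {3,4}: U = 0 and the exact two-sided p is 2/6 = 1/3 by
    enumeration of all six group assignments."""
    u, p = compare_duration_distributions([1.0, 2.0], [3.0, 4.0])
    assert u == 0.0
    assert p == pytest.approx(1.0 / 3.0)


def test_mann_whitney_identical_samples_p_one():
    u, p = compare_duration_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0)


def test_mann_whitney_symmetry():
    a = [1.0, 5.0, 2.5, 7.0]
    b = [3.0, 4.0, 9.0]
    u_ab, p_ab = compare_duration_distributions(a, b)
    u_ba, p_ba = compare_duration_distributions(b, a)
    assert u_ab + u_ba == pytest.approx(len(a) * len(b))
    assert p_ab == pytest.approx(p_ba)


def test_mann_whitney_matches_scipy_exact_no_ties():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 8)
    b = rng.normal(0.5, 1, 7)
    u, p = compare_duration_distributions(a, b)
    ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    assert u == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_mann_whitney_large_sample_matches_scipy_asymptotic():
    rng = np.random.default_rng(6)
    a = np.round(rng.normal(0, 1, 40), 1)  # rounding creates ties
    b = np.round(rng.normal(0.4, 1, 35), 1)
    u, p = compare_duration_distributions(a, b)
    ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert u == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, rel=1e-6)


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        compare_duration_distributions([], [1.0])


def test_3t3_vs_pc3_dwell_distributions_differ(movie_spec):
    """3T3 cells spend longer (and more often > 14 h) in the
    double-positive state than PC3; Mann-Whitney p < 0.01 at n = 50."""
    dwells = {}
    for name in ("t3t3_fullserum", "pc3_hotel"):
        lin = atcq.simulate_population(
            atcq.get_profile(name), 30, movie_spec, seed=15, with_positions=False
        )
        d = [r.dp_dwell_h for r in lin.records if r.dp_dwell_h is not None]
        dwells[name] = d[:50]
    u, p = compare_duration_distributions(dwells["t3t3_fullserum"], dwells["pc3_hotel"])
    assert len(dwells["t3t3_fullserum"]) == len(dwells["pc3_hotel"]) == 50
    assert p < 0.01
    assert np.mean(dwells["t3t3_fullserum"]) > np.mean(dwells["pc3_hotel"])


# ---------------------------------------------------------------------------
# division timing
# ---------------------------------------------------------------------------


def test_no_divisions_zero_histogram():
    counts, edges = division_timing_profile([], 24.0, 72.0)
    assert counts.tolist() == [0, 0, 0]


def test_uniform_division_times_fill_bins_evenly():
    rng = np.random.default_rng(7)
    times = rng.uniform(0, 72, 3000)
    counts, _ = division_timing_profile(times, 24.0, 72.0)
    # chi-square goodness of fit against the uniform expectation
    chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
    assert chi2 < sps.chi2.ppf(0.999, df=2)


def test_window_must_divide_span():
    with pytest.raises(ValueError):
        division_timing_profile([1.0], 30.0, 72.0)
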