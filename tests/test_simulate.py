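"""Simulator: event-order invariants, fate frequencies, determinism,
reporter kinetics."""

import numpy as np
import pytest

import atcq
from atcq.simulate import assign_daughter_fates, reporter_level


@pytest.fixture(scope="module")
def small_spec():
    return atcq.MovieSpec()


def test_zero_founders_gives_empty_lineage(hotel_profile, small_spec):
    lin = atcq.simulate_population(hotel_profile, 0, small_spec, seed=1)
    assert len(lin) == 0
    assert lin.positions_dataframe().empty


def test_negative_founders_rejected(hotel_profile, small_spec):
    with pytest.raises(ValueError):
        atcq.simulate_population(hotel_profile, -1, small_spec, seed=1)


def test_forced_sync_g0_never_divides(small_spec):
    prof = atcq.get_profile(
        "pc3_hotel",
        p_spontaneous_g0=1.0,
        pair_fate_probs=(1.0, 0.0, 0.0),
        founder_spread_h=0.0,
    )
    lin = atcq.simulate_population(prof, 20, small_spec, seed=2, with_positions=False)
    for rec in lin:
        assert rec.venus_off_h is None
        assert rec.division_h is None
        assert rec.fate == "SPONT_G0"


def test_bit_identical_reruns(hotel_profile, small_spec):
    a = atcq.simulate_population(hotel_profile, 8, small_spec, seed=9)
    b = atcq.simulate_population(hotel_profile, 8, small_spec, seed=9)
    assert a.cells_dataframe().equals(b.cells_dataframe())
    assert a.positions_dataframe().equals(b.positions_dataframe())


def test_event_order_invariance(small_spec):
    """Venus on < Cherry on < Venus off < Cherry off < division, for every
    non-silent cycling cell."""
    for name in ("pc3_hotel", "t3t3_fullserum"):
        lin = atcq.simulate_population(
            atcq.get_profile(name), 60, small_spec, seed=4, with_positions=False
        )
        for r in lin:
            seq = [r.venus_on_h, r.cherry_on_h, r.venus_off_h, r.cherry_off_h, r.division_h]
            present = [t for t in seq if t is not None]
            assert present == sorted(present)
            assert r.birth_h <= (r.venus_on_h if r.venus_on_h is not None else r.birth_h)


def test_censoring_conservation(hotel_profile, small_spec):
    """Every record ends at division or at the movie end, never both."""
    lin = atcq.simulate_population(hotel_profile, 40, small_spec, seed=5, with_positions=False)
    for r in lin:
        if r.division_h is not None:
            assert r.censored_end_h == r.division_h
            kids = [c for c in lin if c.parent_id == r.cell_id]
            assert len(kids) == 2
            assert all(k.birth_h == r.division_h for k in kids)
        else:
            assert r.censored_end_h == small_spec.duration_h


def test_hotel_marginal_spontaneous_fraction(hotel_profile, small_spec):
    """Fraction of post-mitotic cells with DP dwell > 14 h matches the
    profile's p_spontaneous_g0 within the binomial 95% CI (pooled over
    seeds, as in the replicate design of the simulated experiments)."""
    n_spont = n_tot = 0
    for seed in (1, 2, 3):
        lin = atcq.simulate_population(
            hotel_profile, 800, small_spec, seed=seed, with_positions=False
        )
        dwells = np.array([r.dp_dwell_h for r in lin if r.dp_dwell_h is not None])
        n_spont += int((dwells > 14).sum())
        n_tot += len(dwells)
    p = hotel_profile.p_spontaneous_g0
    # 99% band: a frozen-seed check should have a low false-alarm rate
    ci = 2.58 * np.sqrt(p * (1 - p) / n_tot)
    assert n_spont / n_tot == pytest.approx(p, abs=ci + 1e-9)


def test_assign_fates_degenerate_async():
    prof = atcq.get_profile(
        "pc3_hotel",
        pair_fate_probs=(0.0, 0.0, 1.0),
        async_delta={"dist": "constant", "value": 3.0},
    )
    rng = np.random.default_rng(0)
    for _ in range(20):
        pf = assign_daughter_fates(prof, rng)
        assert pf.category == "ASYNC"
        assert pf.delta_h == 3.0
        e1 = sum(pf.onsets_d1) + pf.dwell_d1
        e2 = sum(pf.onsets_d2) + pf.dwell_d2
        assert abs(abs(e1 - e2) - 3.0) < 1e-9


def test_assign_fates_sync_g1_tolerance():
    prof = atcq.get_profile("pc3_hotel", pair_fate_probs=(0.0, 1.0, 0.0))
    rng = np.random.default_rng(1)
    for _ in range(50):
        pf = assign_daughter_fates(prof, rng)
        assert pf.category == "SYNC_G1"
        e1 = sum(pf.onsets_d1) + pf.dwell_d1
        e2 = sum(pf.onsets_d2) + pf.dwell_d2
        assert abs(e1 - e2) <= prof.sync_delta_max_h + 1e-9


def test_assign_fates_async_delta_mean_3t3():
    """Asynchronous G1-entry deltas are uniform on [1, 15] h for the 3T3
    profile, so the Monte-Carlo mean is ~8 h (within 3 standard errors)."""
    prof = atcq.get_profile("t3t3_fullserum")
    rng = np.random.default_rng(2)
    deltas = [
        pf.delta_h for _ in range(10_000)
        if (pf := assign_daughter_fates(prof, rng)).category == "ASYNC"
    ]
    se = (14.0 / np.sqrt(12.0)) / np.sqrt(len(deltas))
    assert np.mean(deltas) == pytest.approx(8.0, abs=3 * se)


def test_fate_frequencies_converge(hotel_profile):
    rng = np.random.default_rng(3)
    n = 3000
    counts = {"SYNC_G0": 0, "SYNC_G1": 0, "ASYNC": 0}
    for _ in range(n):
        counts[assign_daughter_fates(hotel_profile, rng).category] += 1
    for p_true, cat in zip(hotel_profile.pair_fate_probs, ("SYNC_G0", "SYNC_G1", "ASYNC")):
        ci = 1.96 * np.sqrt(p_true * (1 - p_true) / n)
        assert counts[cat] / n == pytest.approx(p_true, abs=ci + 1e-9)


# ---------------------------------------------------------------------------
# reporter kinetics
# ---------------------------------------------------------------------------


def _record(**kw):
    base = dict(
        cell_id=0, parent_id=None, birth_h=0.0, venus_on_h=2.0, cherry_on_h=4.0,
        venus_off_h=10.0, cherry_off_h=20.0, division_h=None, censored_end_h=72.0,
        fate="TRANSIENT_G0_TO_G1",
    )
    base.update(kw)
    return atcq.CellRecord(**base)


def test_reporter_level_zero_before_onset(hotel_profile):
    rec = _record()
    assert reporter_level(rec, 1.0, "venus", hotel_profile) == 0.0
    assert reporter_level(rec, 1.0, "cherry", hotel_profile) == 0.0


def test_reporter_level_fall_midpoint(hotel_profile):
    rec = _record()
    mid = rec.venus_off_h + hotel_profile.venus_fall_h / 2
    assert reporter_level(rec, mid, "venus", hotel_profile) == pytest.approx(0.5)


def test_reporter_level_g0_plateau(hotel_profile):
    rec = _record(venus_off_h=None, cherry_off_h=None, fate="SPONT_G0")
    assert reporter_level(rec, 60.0, "venus", hotel_profile) == 1.0
    assert reporter_level(rec, 60.0, "cherry", hotel_profile) == 1.0


def test_reporter_level_outside_life_rejected(hotel_profile):
    rec = _record()
    with pytest.raises(ValueError):
        reporter_level(rec, -1.0, "venus", hotel_profile)
    with pytest.raises(ValueError):
        reporter_level(rec, 100.0, "venus", hotel_profile)
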