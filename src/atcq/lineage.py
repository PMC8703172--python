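"""Daughter-pair fate classification and population-level summaries.

After a mitosis the two daughters may both stay in a prolonged
double-positive G0 (synchronous G0), both degrade Venus and enter G1 within
a small tolerance of each other (synchronous G1), or make an asynchronous
proliferation-quiescence decision: one daughter enters G1 while its sibling
remains in G0, or their G1-entry times differ beyond tolerance.  This module
scores those categories from per-daughter :class:`~atcq.classification.
CellCycleCall` objects, quantifies asynchrony deltas, summarises population
quiescence statistics and compares dwell-time distributions by
Mann-Whitney U.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .classification import CellCycleCall, ClassifierConfig

__all__ = [
    "DaughterPairCall",
    "PopulationSummary",
    "classify_daughter_pair",
    "asynchrony_delta",
    "summarize_population",
    "compare_duration_distributions",
    "division_timing_profile",
]

PAIR_CATEGORIES = ("SYNC_G0", "SYNC_G1", "ASYNC", "UNDETERMINED")


@dataclass
class DaughterPairCall:
    """Scored proliferation-quiescence decision of one daughter pair."""

    parent_track_id: int
    category: str
    division_time_h: float
    delta_g1_entry_h: Optional[float] = None
    censored_delta: bool = False


@dataclass
class PopulationSummary:
    """Population-level quiescence statistics.

    ``percent_spontaneous_g0`` uses cells classifiable as post-mitotic with
    at least ``min_followup_h`` of potential observation (unbiased censoring
    denominator); ``percent_divided`` uses tracks observable at least
    ``min_followup_h``.
    """

    n_tracked: int = 0
    n_divided: int = 0
    percent_divided: float = float("nan")
    n_classifiable_postmitotic: int = 0
    n_spontaneous_g0: int = 0
    percent_spontaneous_g0: float = float("nan")
    n_transient_g0: int = 0
    percent_transient_g0: float = float("nan")
    dp_durations_h: list[float] = field(default_factory=list)
    division_times_h: list[float] = field(default_factory=list)
    pair_counts: dict[str, int] = field(default_factory=dict)
    percent_async_pairs: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_tracked": self.n_tracked,
            "n_divided": self.n_divided,
            "percent_divided": self.percent_divided,
            "n_classifiable_postmitotic": self.n_classifiable_postmitotic,
            "n_spontaneous_g0": self.n_spontaneous_g0,
            "percent_spontaneous_g0": self.percent_spontaneous_g0,
            "n_transient_g0": self.n_transient_g0,
            "percent_transient_g0": self.percent_transient_g0,
            "pair_counts": dict(self.pair_counts),
            "percent_async_pairs": self.percent_async_pairs,
            "mean_dp_duration_h": (
                float(np.mean(self.dp_durations_h)) if self.dp_durations_h else float("nan")
            ),
        }


def _is_spontaneous(call: CellCycleCall) -> bool:
    return bool(call.classifiable and call.spontaneous_g0)


def classify_daughter_pair(
    call_d1: CellCycleCall,
    call_d2: CellCycleCall,
    config: ClassifierConfig | None = None,
    parent_track_id: int = -1,
    division_time_h: float = float("nan"),
    observation_end_h: Optional[float] = None,
) -> DaughterPairCall:
    """Score one daughter pair.

    ``SYNC_G0``: both daughters spontaneous (or censored in a
    beyond-threshold DP).  ``SYNC_G1``: both entered G1 with
    ``|delta| <= sync_tolerance_h``.  ``ASYNC``: both entered with a larger
    delta, or exactly one entered while the sibling was verifiably still in
    G0: the sibling must have been double positive for at least
    ``transient_threshold_h`` when its sister entered G1, and (when
    ``observation_end_h`` is given) its trace must reach the end of the
    observation window — a sibling whose track was simply lost mid-phase is
    not evidence of asynchrony.  Everything else is ``UNDETERMINED``.
    """
    config = config or ClassifierConfig()
    pc = DaughterPairCall(parent_track_id, "UNDETERMINED", division_time_h)
    c1, c2 = call_d1, call_d2
    e1 = c1.g1_entry_h if c1.classifiable else None
    e2 = c2.g1_entry_h if c2.classifiable else None
    s1, s2 = _is_spontaneous(c1), _is_spontaneous(c2)
    if s1 and s2:
        pc.category = "SYNC_G0"
        return pc
    if e1 is not None and e2 is not None:
        # compare entries at the mid-level crossing when available: the
        # constant mid-to-fall-start offset cancels in the difference and
        # its measurement noise is several-fold smaller
        m1 = c1.g1_entry_mid_h if c1.g1_entry_mid_h is not None else e1
        m2 = c2.g1_entry_mid_h if c2.g1_entry_mid_h is not None else e2
        delta = abs(m1 - m2)
        pc.delta_g1_entry_h = delta
        pc.category = "SYNC_G1" if delta <= config.sync_tolerance_h else "ASYNC"
        return pc
    # exactly one daughter entered G1
    for entered, other, t_entry in ((c1, c2, e1), (c2, c1, e2)):
        if t_entry is None:
            continue
        if _is_spontaneous(other):
            pc.category = "ASYNC"
            pc.censored_delta = other.g1_entry_h is None
            return pc
        # censored sibling: require it to have verifiably been in DP at least
        # transient_threshold_h when its sister entered G1, and observed
        # through the end of the window (not a mid-movie track loss)
        observed_through = True
        if observation_end_h is not None:
            observed_through = (
                other.trace_end_h is not None
                and other.trace_end_h >= observation_end_h - 1.0
            )
        if (
            other.censored_dp
            and observed_through
            and other.dp_start_h is not None
            and t_entry - other.dp_start_h >= config.transient_threshold_h
        ):
            pc.category = "ASYNC"
            pc.censored_delta = True
            return pc
    return pc


def asynchrony_delta(pair: DaughterPairCall) -> Optional[float]:
    """G1-entry time difference for an asynchronous pair; ``None`` when one
    daughter never entered within observation (right-censored delta)."""
    if pair.category != "ASYNC":
        return None
    return pair.delta_g1_entry_h


def summarize_population(
    calls: Sequence[CellCycleCall],
    pairs: Sequence[DaughterPairCall] = (),
    config: ClassifierConfig | None = None,
    observation_spans: Optional[dict[int, tuple[float, float]]] = None,
    division_times: Sequence[float] = (),
) -> PopulationSummary:
    """Aggregate per-cell calls and per-pair calls into population statistics.

    ``observation_spans`` maps track_id to (start_h, end_h) of potential
    observation; tracks observable less than ``min_followup_h`` are excluded
    from the spontaneous-G0 and percent-divided denominators.
    """
    config = config or ClassifierConfig()
    s = PopulationSummary()
    s.n_tracked = len(calls)
    if len(calls) == 0 and len(pairs) == 0:
        return s

    def followup_ok(call: CellCycleCall) -> bool:
        if observation_spans is None:
            return True
        span = observation_spans.get(call.track_id)
        if span is None:
            return True
        return (span[1] - span[0]) >= config.min_followup_h

    eligible = [c for c in calls if c.classifiable and followup_ok(c)]
    s.n_classifiable_postmitotic = len(eligible)
    s.n_spontaneous_g0 = sum(1 for c in eligible if c.spontaneous_g0)
    s.n_transient_g0 = sum(1 for c in eligible if c.transient_g0)
    if eligible:
        s.percent_spontaneous_g0 = 100.0 * s.n_spontaneous_g0 / len(eligible)
        s.percent_transient_g0 = 100.0 * s.n_transient_g0 / len(eligible)
    s.dp_durations_h = [
        float(c.dp_duration_h)
        for c in eligible
        if c.dp_duration_h is not None and not c.censored_dp
    ]
    s.division_times_h = [float(t) for t in division_times]
    s.n_divided = len(division_times)
    if observation_spans is not None:
        denom = sum(
            1
            for tid, (a, b) in observation_spans.items()
            if (b - a) >= config.min_followup_h
        )
        if denom:
            s.percent_divided = 100.0 * s.n_divided / denom
    s.pair_counts = {k: 0 for k in PAIR_CATEGORIES}
    for p in pairs:
        s.pair_counts[p.category] = s.pair_counts.get(p.category, 0) + 1
    scored = sum(s.pair_counts[k] for k in ("SYNC_G0", "SYNC_G1", "ASYNC"))
    if scored:
        s.percent_async_pairs = 100.0 * s.pair_counts["ASYNC"] / scored
    return s


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample ``a`` with midrank treatment of ties."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def compare_duration_distributions(
    durations_a: Sequence[float], durations_b: Sequence[float],
    exact_max_n: int = 20,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two dwell-time samples.

    Exact enumeration of all group relabelings (with midranks for ties) when
    the combined sample size is at most ``exact_max_n``; otherwise the
    normal approximation with tie correction and continuity correction.
    Symmetric in its arguments up to ``U <-> n1*n2 - U``.
    """
    a = np.asarray(list(durations_a), dtype=float)
    b = np.asarray(list(durations_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    u = _u_statistic(a, b)
    mean_u = n1 * n2 / 2.0
    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([a, b])
        dev_obs = abs(u - mean_u)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u_perm - mean_u) >= dev_obs - 1e-12:
                count += 1
            total += 1
        return u, count / total
    # normal approximation with tie correction
    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return u, 1.0
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = 2.0 * _sps.norm.sf(z)
    return u, min(p, 1.0)


def division_timing_profile(
    division_times_h: Sequence[float], window_h: float, span_h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of division times in bins of ``window_h`` over
    ``[0, span_h]``; returns (counts, bin_edges)."""
    if window_h <= 0 or span_h <= 0:
        raise ValueError("window and span must be positive")
    n_bins = int(round(span_h / window_h))
    if abs(n_bins * window_h - span_h) > 1e-9:
        raise ValueError("window_h must divide span_h")
    edges = np.linspace(0.0, span_h, n_bins + 1)
    counts, _ = np.histogram(np.asarray(list(division_times_h), dtype=float), bins=edges)
    return counts, edges
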