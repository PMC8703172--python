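"""Shared fixtures: small rendered movies and their ground truth.

Everything is generated at test time from the synthetic-data module; the
expensive rendered-field fixture is session-scoped and reused by the
segmentation, tracking and end-to-end tests.
"""

from __future__ import annotations

import pytest

import atcq
from atcq.validation import match_detections_to_truth


@pytest.fixture(scope="session")
def movie_spec() -> atcq.MovieSpec:
    return atcq.MovieSpec()


@pytest.fixture(scope="session")
def hotel_profile():
    return atcq.get_profile("pc3_hotel")


@pytest.fixture(scope="session")
def hotel_field(hotel_profile, movie_spec):
    """One rendered cell-hotel field (10 founders, 72 h) plus ground truth."""
    lineage = atcq.simulate_population(hotel_profile, 10, movie_spec, seed=3)
    stack, truth_positions = atcq.render_movie(
        lineage, movie_spec, seed=4, profile=hotel_profile
    )
    return lineage, stack, truth_positions


@pytest.fixture(scope="session")
def hotel_analysis(hotel_field, movie_spec):
    """Blind pipeline output on the rendered field, with truth matching."""
    lineage, stack, truth_positions = hotel_field
    res = atcq.analyze_stack(stack, movie_spec.frame_interval_h)
    matched = match_detections_to_truth(res.detections, truth_positions)
    return res, matched


def noiseless_trace(record, profile, spec, basal=0.03):
    """Deterministic reporter trace of one simulated cell."""
    t, v, c = atcq.trace_arrays_from_record(record, profile, spec, basal=basal)
    return atcq.ReporterTrace(times=t, venus=v, cherry=c, track_id=record.cell_id)
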