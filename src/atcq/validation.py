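"""Ground-truth comparison helpers for synthetic movies.

Used to score segmentation recall/precision, frame-to-frame link accuracy
and division recovery against the simulator's truth tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tracking import Track

__all__ = [
    "match_detections_to_truth",
    "detection_scores",
    "link_accuracy",
    "match_tracks_to_truth",
    "division_recovery",
]


def match_detections_to_truth(
    detections: pd.DataFrame, truth_positions: pd.DataFrame, max_dist: float = 3.0
) -> pd.DataFrame:
    """Greedy nearest-neighbour matching of detections to truth per frame.

    Returns the detections table with a ``cell_id`` column (-1 = unmatched).
    """
    det = detections.copy()
    det["cell_id"] = -1
    truth_by_frame = dict(tuple(truth_positions.groupby("frame")))
    for f, g in det.groupby("frame_index"):
        tg = truth_by_frame.get(f)
        if tg is None or len(tg) == 0:
            continue
        d = np.linalg.norm(
            g[["x", "y"]].to_numpy()[:, None, :] - tg[["x", "y"]].to_numpy()[None, :, :],
            axis=2,
        )
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        used_i: set[int] = set()
        used_j: set[int] = set()
        for i, j in order:
            if d[i, j] > max_dist:
                break
            if i in used_i or j in used_j:
                continue
            used_i.add(int(i))
            used_j.add(int(j))
            det.loc[g.index[i], "cell_id"] = int(tg.iloc[j]["cell_id"])
    return det


def detection_scores(
    detections: pd.DataFrame, truth_positions: pd.DataFrame, max_dist: float = 3.0
) -> tuple[float, float]:
    """(recall, precision) of detections against truth centroids."""
    matched = match_detections_to_truth(detections, truth_positions, max_dist)
    n_match = int((matched["cell_id"] >= 0).sum())
    recall = n_match / len(truth_positions) if len(truth_positions) else 1.0
    precision = n_match / len(matched) if len(matched) else 1.0
    return recall, precision


def link_accuracy(
    tracks: list[Track],
    detections_matched: pd.DataFrame,
) -> float:
    """Fraction of consecutive frame-to-frame links joining the same truth
    cell.  ``detections_matched`` must carry the ``cell_id`` column from
    :func:`match_detections_to_truth`."""
    lookup = {
        (int(r.frame_index), round(float(r.x), 4), round(float(r.y), 4)): int(r.cell_id)
        for r in detections_matched.itertuples(index=False)
    }

    def cell_of(track: Track, k: int) -> int:
        return lookup.get(
            (track.frames[k], round(track.xs[k], 4), round(track.ys[k], 4)), -1
        )

    good = total = 0
    for t in tracks:
        for k in range(len(t) - 1):
            if t.frames[k + 1] != t.frames[k] + 1:
                continue  # gap-closed link, not a frame-to-frame link
            c0, c1 = cell_of(t, k), cell_of(t, k + 1)
            if c0 < 0 or c1 < 0:
                continue
            total += 1
            good += int(c0 == c1)
    return good / total if total else 1.0


def match_tracks_to_truth(
    tracks: list[Track], detections_matched: pd.DataFrame
) -> dict[int, int]:
    """Majority-vote assignment of each track to a truth cell id."""
    lookup = {
        (int(r.frame_index), round(float(r.x), 4), round(float(r.y), 4)): int(r.cell_id)
        for r in detections_matched.itertuples(index=False)
    }
    out: dict[int, int] = {}
    for t in tracks:
        votes: dict[int, int] = {}
        for k in range(len(t)):
            c = lookup.get((t.frames[k], round(t.xs[k], 4), round(t.ys[k], 4)), -1)
            if c >= 0:
                votes[c] = votes.get(c, 0) + 1
        if votes:
            out[t.track_id] = max(sorted(votes), key=lambda c: votes[c])
    return out


def division_recovery(
    tracks: list[Track],
    track_to_cell: dict[int, int],
    truth_cells: pd.DataFrame,
    min_daughter_h: float = 1.5,
) -> float:
    """Fraction of observable ground-truth divisions recovered with the
    correct parent and both daughters (by truth identity).

    A division is observable when it happens inside the movie and both
    daughters live at least ``min_daughter_h`` before censoring.
    """
    life = {
        int(r.cell_id): (r.birth_h, r.censored_end_h)
        for r in truth_cells.itertuples(index=False)
    }
    truth_children: dict[int, set[int]] = {}
    for r in truth_cells.itertuples(index=False):
        if pd.isna(r.parent_id):
            continue
        if r.birth_h < 0 or (r.censored_end_h - r.birth_h) < min_daughter_h:
            continue
        truth_children.setdefault(int(r.parent_id), set()).add(int(r.cell_id))
    truth_divisions = {p: kids for p, kids in truth_children.items() if len(kids) == 2}
    if not truth_divisions:
        return 1.0
    recovered = 0
    by_id = {t.track_id: t for t in tracks}
    for t in tracks:
        if len(t.child_track_ids) != 2:
            continue
        p = track_to_cell.get(t.track_id)
        kids = {
            track_to_cell.get(c) for c in t.child_track_ids if c in by_id
        }
        if p in truth_divisions and kids == truth_divisions[p]:
            recovered += 1
    return recovered / len(truth_divisions)
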