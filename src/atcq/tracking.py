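"""Frame-to-frame linking, gap closing, division detection and trace
extraction.

Linking is a per-frame-pair optimal (Hungarian) assignment on centroid
distance with a hard displacement gate; a greedy nearest-neighbour variant is
available for speed.  Track ends may be joined to later track starts within
``max_gap`` frames (gap closing).  Divisions are recovered in two ways:

* an ended track with two new track starts inside ``division_radius``, and
* the common case where the linker has silently continued the parent track
  into one daughter: a new start next to a continuing track causes the
  continuing track to be *split* at that frame, yielding one parent and two
  daughter tracks.

Every detection belongs to at most one track; a parent has exactly two
children; lineage trees are acyclic by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Track",
    "TrackingParams",
    "link_detections",
    "detect_divisions",
    "track_detections",
    "extract_trace",
    "tracks_dataframe",
    "lineage_dataframe",
]


@dataclass(frozen=True)
class TrackingParams:
    """Linking parameters (pixels and frames).

    ``max_gap`` (default 4 frames, ~2 h at 0.5 h sampling) bridges brief
    detection dropouts around mitosis; ``division_radius`` defaults to
    6x the PSF sigma — newborn daughters sit one spot radius from the
    parent centroid but may go undetected for a frame or two while they
    separate, so the radius must cover the separation at first detection.
    ``min_track_len`` marks tracks too short for downstream classification.
    """

    max_displacement: float = 8.0
    max_gap: int = 4
    division_radius: Optional[float] = None
    psf_sigma: float = 2.0
    min_track_len: int = 6
    method: str = "hungarian"

    def __post_init__(self) -> None:
        if self.max_displacement <= 0 or self.max_gap < 0 or self.min_track_len < 1:
            raise ValueError("invalid tracking parameters")
        if self.division_radius is not None and self.division_radius <= 0:
            raise ValueError("division_radius must be positive")
        if self.method not in ("hungarian", "greedy"):
            raise ValueError(f"unknown linking method {self.method!r}")

    @property
    def div_radius(self) -> float:
        return self.division_radius if self.division_radius is not None else 6.0 * self.psf_sigma


@dataclass
class Track:
    """An ordered sequence of detections with optional lineage links."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    xs: list[float] = field(default_factory=list)
    ys: list[float] = field(default_factory=list)
    venus: list[float] = field(default_factory=list)
    cherry: list[float] = field(default_factory=list)
    parent_track_id: Optional[int] = None
    child_track_ids: list[int] = field(default_factory=list)

    @property
    def start_frame(self) -> int:
        return self.frames[0]

    @property
    def end_frame(self) -> int:
        return self.frames[-1]

    def __len__(self) -> int:
        return len(self.frames)

    def append(self, frame: int, x: float, y: float, v: float, c: float) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("frames must be strictly increasing within a track")
        self.frames.append(frame)
        self.xs.append(x)
        self.ys.append(y)
        self.venus.append(v)
        self.cherry.append(c)


def _frame_groups(detections: pd.DataFrame) -> dict[int, pd.DataFrame]:
    return {
        int(f): g.sort_values("label", kind="stable").reset_index(drop=True)
        for f, g in detections.groupby("frame_index")
    }


def _assign(prev_xy: np.ndarray, cur_xy: np.ndarray, max_disp: float, method: str):
    """One-to-one matches (i_prev, j_cur) with distance <= max_disp."""
    if len(prev_xy) == 0 or len(cur_xy) == 0:
        return []
    d = np.linalg.norm(prev_xy[:, None, :] - cur_xy[None, :, :], axis=2)
    matches = []
    if method == "hungarian":
        cost = np.where(d <= max_disp, d, 1e6)
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if d[i, j] <= max_disp:
                matches.append((int(i), int(j)))
    else:  # greedy nearest neighbour, deterministic order
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        used_i: set[int] = set()
        used_j: set[int] = set()
        for i, j in order:
            if d[i, j] > max_disp:
                break
            if i in used_i or j in used_j:
                continue
            used_i.add(int(i))
            used_j.add(int(j))
            matches.append((int(i), int(j)))
    return matches


def link_detections(
    detections: pd.DataFrame, params: TrackingParams | None = None
) -> list[Track]:
    """Link a detections table into tracks (with gap closing, no lineage)."""
    params = params or TrackingParams()
    tracks: list[Track] = []
    if detections is None or len(detections) == 0:
        return tracks
    groups = _frame_groups(detections)
    active: list[Track] = []  # tracks whose last frame is the previous frame
    last_frame = None
    for f in sorted(groups):
        g = groups[f]
        cur_xy = g[["x", "y"]].to_numpy(dtype=float)
        if last_frame is not None and f == last_frame + 1 and active:
            prev_xy = np.array([[t.xs[-1], t.ys[-1]] for t in active])
            matches = _assign(prev_xy, cur_xy, params.max_displacement, params.method)
        else:
            matches = []
        matched_tracks = set()
        matched_dets = set()
        for i, j in matches:
            active[i].append(
                f,
                float(g.x[j]),
                float(g.y[j]),
                float(g.mean_venus[j]),
                float(g.mean_cherry[j]),
            )
            matched_tracks.add(i)
            matched_dets.add(j)
        next_active = [t for i, t in enumerate(active) if i in matched_tracks]
        for j in range(len(g)):
            if j not in matched_dets:
                t = Track(track_id=len(tracks))
                t.append(
                    f,
                    float(g.x[j]),
                    float(g.y[j]),
                    float(g.mean_venus[j]),
                    float(g.mean_cherry[j]),
                )
                tracks.append(t)
                next_active.append(t)
        # tracks not extended fall out of the active set (may be gap-closed)
        active = next_active
        last_frame = f
    _close_gaps(tracks, params)
    return [t for t in tracks if len(t) > 0]


def _close_gaps(tracks: list[Track], params: TrackingParams) -> None:
    """Join track ends to later track starts within the gap window, greedily
    by distance.  The joined start-track is emptied in place."""
    if params.max_gap < 2:
        return
    candidates = []
    for a in tracks:
        if not a.frames:
            continue
        for b in tracks:
            if a is b or not b.frames:
                continue
            gap = b.start_frame - a.end_frame
            if 2 <= gap <= params.max_gap:
                dist = float(
                    np.hypot(b.xs[0] - a.xs[-1], b.ys[0] - a.ys[-1])
                )
                if dist <= params.max_displacement * gap:
                    candidates.append((dist, a.track_id, b.track_id, a, b))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used_ends: set[int] = set()
    used_starts: set[int] = set()
    for dist, aid, bid, a, b in candidates:
        if aid in used_ends or bid in used_starts or aid in used_starts or bid in used_ends:
            continue
        used_ends.add(aid)
        used_starts.add(bid)
        for k in range(len(b.frames)):
            a.append(b.frames[k], b.xs[k], b.ys[k], b.venus[k], b.cherry[k])
        b.frames, b.xs, b.ys, b.venus, b.cherry = [], [], [], [], []


def detect_divisions(
    tracks: list[Track], params: TrackingParams | None = None
) -> list[Track]:
    """Annotate (and where needed split) tracks with parent/daughter links.

    Candidates are ranked by summed centroid distance and adopted greedily
    without overlap; a parent never gains more than two children.  Returns
    the updated track list (splits append new tracks).
    """
    params = params or TrackingParams()
    tracks = [t for t in tracks if len(t) > 0]
    radius = params.div_radius
    by_id = {t.track_id: t for t in tracks}
    next_id = max(by_id) + 1 if by_id else 0

    # a linked chain may host several divisions; splits create new segments
    # that stay associated with the chain of the original track
    root_of = {t.track_id: t.track_id for t in tracks}
    chains = {t.track_id: [t.track_id] for t in tracks}

    def segments(pid: int) -> list[Track]:
        return [by_id[q] for q in chains[root_of[pid]]]

    # Candidate divisions: (cost, kind, parent_track_id, start_track_id,
    # frame).  The cost is the minimum distance between the new start and
    # the candidate parent's positions over a short lookback window: a
    # newborn daughter appears near the *pre-division* parent centroid even
    # when it went undetected for a frame or two, whereas an unrelated
    # neighbouring track never gets that close.
    candidates: list[tuple[float, str, int, int, int]] = []
    for s in tracks:
        ts = s.start_frame
        if ts == 0:
            continue
        sx, sy = s.xs[0], s.ys[0]
        for x in tracks:
            if x is s:
                continue
            gap = ts - x.end_frame
            if 1 <= gap <= params.max_gap:
                # (a) ended track; needs a second free start at selection time
                k1 = len(x.frames)
                k0 = max(0, k1 - params.max_gap - 1)
                d = min(
                    float(np.hypot(sx - x.xs[k], sy - x.ys[k])) for k in range(k0, k1)
                )
                if d <= radius:
                    candidates.append((d, "end", x.track_id, s.track_id, x.end_frame))
            elif x.start_frame < ts <= x.end_frame:
                # (b) continuing track that silently carries one daughter
                try:
                    k = x.frames.index(ts - 1)
                except ValueError:
                    continue
                if k + 1 >= len(x.frames) or x.frames[k + 1] != ts:
                    continue
                k0 = max(0, k - params.max_gap)
                d = min(
                    float(np.hypot(sx - x.xs[j], sy - x.ys[j])) for j in range(k0, k + 1)
                )
                d2 = float(np.hypot(x.xs[k + 1] - x.xs[k], x.ys[k + 1] - x.ys[k]))
                if d <= radius and d2 <= radius:
                    candidates.append((d, "split", x.track_id, s.track_id, ts))
    candidates.sort(key=lambda c: (c[0], c[2], c[3]))

    used_children: set[int] = set()
    end_cands: dict[int, list[tuple[float, int]]] = {}
    for cost, kind, pid, sid, fr in candidates:
        if kind == "end":
            end_cands.setdefault(pid, []).append((cost, sid))

    def split_segment(seg: Track, ts: int) -> Track:
        """Cut ``seg`` before frame ``ts``; the tail inherits its children."""
        nonlocal next_id
        k = seg.frames.index(ts - 1) + 1
        tail = Track(track_id=next_id)
        next_id += 1
        tail.frames = seg.frames[k:]
        tail.xs = seg.xs[k:]
        tail.ys = seg.ys[k:]
        tail.venus = seg.venus[k:]
        tail.cherry = seg.cherry[k:]
        tail.child_track_ids = seg.child_track_ids
        for cid in tail.child_track_ids:
            by_id[cid].parent_track_id = tail.track_id
        seg.frames = seg.frames[:k]
        seg.xs = seg.xs[:k]
        seg.ys = seg.ys[:k]
        seg.venus = seg.venus[:k]
        seg.cherry = seg.cherry[:k]
        seg.child_track_ids = []
        tail.parent_track_id = seg.track_id
        tracks.append(tail)
        by_id[tail.track_id] = tail
        root = root_of[seg.track_id]
        root_of[tail.track_id] = root
        chains[root].append(tail.track_id)
        return tail

    for cost, kind, pid, sid, fr in candidates:
        child = by_id[sid]
        if sid in used_children or child.parent_track_id is not None:
            continue
        if kind == "split":
            seg = next(
                (s for s in segments(pid) if (fr - 1) in s.frames and fr in s.frames), None
            )
            if seg is None or seg is child:
                continue
            tail = split_segment(seg, fr)
            seg.child_track_ids = [tail.track_id, child.track_id]
            child.parent_track_id = seg.track_id
            used_children.update((sid, tail.track_id))
        else:
            seg = next(
                (s for s in segments(pid) if s.frames and s.end_frame == fr
                 and not s.child_track_ids),
                None,
            )
            if seg is None or seg is child:
                continue
            second = None
            for c2, sid2 in sorted(end_cands.get(pid, [])):
                if (
                    sid2 != sid
                    and sid2 not in used_children
                    and sid2 != seg.track_id
                    and by_id[sid2].parent_track_id is None
                ):
                    second = sid2
                    break
            if second is None:
                continue
            seg.child_track_ids = [sid, second]
            child.parent_track_id = seg.track_id
            by_id[second].parent_track_id = seg.track_id
            used_children.update((sid, second))
    return tracks


def track_detections(
    detections: pd.DataFrame, params: TrackingParams | None = None
) -> list[Track]:
    """Link + gap-close + division detection in one call."""
    params = params or TrackingParams()
    return detect_divisions(link_detections(detections, params), params)


def extract_trace(track: Track, frame_interval_h: float):
    """Convert a track into a :class:`~atcq.classification.ReporterTrace`.

    Missing (gap) frames are filled by linear interpolation and flagged.
    """
    from .classification import ReporterTrace

    if len(track) == 0:
        raise ValueError("empty track")
    frames = np.arange(track.start_frame, track.end_frame + 1)
    t = frames * frame_interval_h
    have = np.isin(frames, track.frames)
    obs_t = np.asarray(track.frames) * frame_interval_h
    venus = np.interp(t, obs_t, np.asarray(track.venus, dtype=float))
    cherry = np.interp(t, obs_t, np.asarray(track.cherry, dtype=float))
    return ReporterTrace(
        times=t,
        venus=venus,
        cherry=cherry,
        track_id=track.track_id,
        interpolated=~have,
    )


def tracks_dataframe(tracks: list[Track], frame_interval_h: float | None = None) -> pd.DataFrame:
    rows = []
    for t in sorted(tracks, key=lambda t: t.track_id):
        obs = set(t.frames)
        for f in range(t.start_frame, t.end_frame + 1):
            if f in obs:
                k = t.frames.index(f)
                rows.append((t.track_id, f, t.xs[k], t.ys[k], t.venus[k], t.cherry[k], False))
            else:
                rows.append((t.track_id, f, np.nan, np.nan, np.nan, np.nan, True))
    df = pd.DataFrame(
        rows,
        columns=["track_id", "frame_index", "x", "y", "mean_venus", "mean_cherry", "interpolated"],
    )
    # fill gap rows by linear interpolation within each track
    for col in ("x", "y", "mean_venus", "mean_cherry"):
        df[col] = df.groupby("track_id")[col].transform(
            lambda s: s.interpolate(method="linear", limit_direction="both")
        )
    return df


def lineage_dataframe(tracks: list[Track]) -> pd.DataFrame:
    rows = [
        (t.track_id, t.parent_track_id, t.start_frame, t.end_frame, len(t))
        for t in sorted(tracks, key=lambda t: t.track_id)
    ]
    return pd.DataFrame(
        rows, columns=["track_id", "parent_track_id", "start_frame", "end_frame", "n_points"]
    ).astype({"track_id": int})
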