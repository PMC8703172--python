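"""Stochastic single-cell reporter/lineage simulator.

Simulates per-cell event times of the dual-reporter state machine under a
:class:`~atcq.profiles.KineticProfile` and turns them into lineage trees with
per-frame positions.  The canonical (cycling) life history of a non-silent
cell born at ``b`` is::

    b --(venus onset delay)--> venus_on --(cherry onset delay)--> cherry_on
      --(DP dwell)--> venus_off --(G1)--> cherry_off --(S/G2/M)--> division

with the double-positive (DP) dwell drawn from the transient or prolonged
distribution according to the cell's fate.  A division always produces
exactly two daughters whose fates are coupled through the daughter-pair
categories (synchronous G0, synchronous G1, asynchronous).  Every record is
censored at the movie end; events at or beyond the censoring time are absent.

Reporter intensities are deterministic piecewise-linear ramps of the event
times (:func:`reporter_level`), expressed as a fraction of the per-channel
peak.  Cells move as an isotropic Gaussian random walk; daughters start one
spot radius from the parent centroid along a random direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .profiles import KineticProfile

__all__ = [
    "MovieSpec",
    "CellRecord",
    "LineageTree",
    "PairFates",
    "simulate_population",
    "assign_daughter_fates",
    "reporter_level",
    "trace_arrays_from_record",
]

FATES = ("SPONT_G0", "TRANSIENT_G0_TO_G1", "DIRECT_G1", "SILENT", "CYCLING")
PAIR_CATEGORIES = ("SYNC_G0", "SYNC_G1", "ASYNC")


@dataclass(frozen=True)
class MovieSpec:
    """Acquisition geometry and camera model for rendered movies.

    Frame interval defaults to 0.5 h (imaging intervals of 20-30 min) over a
    72 h movie.  Intensities are 16-bit counts; the basal intensity is the
    small constitutive signal (default 3 % of peak) that keeps
    reporter-negative cells detectable.
    """

    frame_interval_h: float = 0.5
    duration_h: float = 72.0
    width: int = 256
    height: int = 256
    psf_sigma: float = 2.0
    peak_intensity: tuple[float, float] = (10000.0, 10000.0)
    basal_intensity: float = 300.0
    background_level: float = 100.0
    read_noise_sigma: float = 3.0
    shot_noise: bool = True
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("movie dimensions must be positive")
        if self.frame_interval_h <= 0 or self.duration_h <= 0:
            raise ValueError("frame interval and duration must be positive")
        n = self.duration_h / self.frame_interval_h
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_h must be a multiple of frame_interval_h")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h / self.frame_interval_h))

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_h

    @property
    def spot_radius(self) -> float:
        """Visible spot radius in pixels (2.5 sigma of the PSF)."""
        return 2.5 * self.psf_sigma


@dataclass
class CellRecord:
    """Ground-truth event times, fate and positions for one cell.

    Event times are hours from movie start and may be negative for founders
    born before observation begins.  An event at or beyond
    ``censored_end_h`` is stored as ``None`` (absent).  ``positions`` holds
    the (x, y) pixel centroid for frames ``first_frame ..
    first_frame + len(positions) - 1``.
    """

    cell_id: int
    parent_id: Optional[int]
    birth_h: float
    venus_on_h: Optional[float]
    cherry_on_h: Optional[float]
    venus_off_h: Optional[float]
    cherry_off_h: Optional[float]
    division_h: Optional[float]
    censored_end_h: float
    fate: str
    dp_dwell_h: Optional[float] = None  # realized dwell, uncensored
    first_frame: int = 0
    n_frames_alive: int = 0
    positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    @property
    def divided(self) -> bool:
        return self.division_h is not None

    @property
    def end_h(self) -> float:
        return self.division_h if self.division_h is not None else self.censored_end_h

    def frames(self) -> np.ndarray:
        return self.first_frame + np.arange(self.n_frames_alive)


class PairFates(NamedTuple):
    """Joint fate draw for one daughter pair.

    ``dwell_d1``/``dwell_d2`` are the realized DP dwells in hours and
    ``onsets_d1``/``onsets_d2`` the (Venus delay, Cherry delay) draws;
    ``delta_h`` is the G1-entry time difference for asynchronous pairs
    (``None`` otherwise).  Pair synchrony is defined on *G1-entry times*
    (birth + Venus delay + Cherry delay + dwell), so the lagging daughter's
    dwell absorbs the difference between the siblings' onset draws.
    """

    category: str
    dwell_d1: float
    dwell_d2: float
    delta_h: Optional[float]
    onsets_d1: Optional[tuple[float, float]] = None
    onsets_d2: Optional[tuple[float, float]] = None


@dataclass
class LineageTree:
    """A simulated population: list of :class:`CellRecord` plus provenance."""

    records: list[CellRecord]
    spec: MovieSpec
    profile_name: str
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self) -> dict[int, CellRecord]:
        return {r.cell_id: r for r in self.records}

    def fate_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.fate] = out.get(r.fate, 0) + 1
        return dict(sorted(out.items()))

    def cells_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "cell_id": r.cell_id,
                    "parent_id": r.parent_id,
                    "birth_h": r.birth_h,
                    "venus_on_h": r.venus_on_h,
                    "cherry_on_h": r.cherry_on_h,
                    "venus_off_h": r.venus_off_h,
                    "cherry_off_h": r.cherry_off_h,
                    "division_h": r.division_h,
                    "censored_end_h": r.censored_end_h,
                    "dp_dwell_h": r.dp_dwell_h,
                    "fate": r.fate,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "cell_id",
                "parent_id",
                "birth_h",
                "venus_on_h",
                "cherry_on_h",
                "venus_off_h",
                "cherry_off_h",
                "division_h",
                "censored_end_h",
                "dp_dwell_h",
                "fate",
            ],
        )

    def positions_dataframe(self) -> pd.DataFrame:
        frames, ids, xs, ys = [], [], [], []
        for r in self.records:
            if len(r.positions) != r.n_frames_alive:
                continue  # simulated without positions
            f = r.frames()
            frames.append(f)
            ids.append(np.full(len(f), r.cell_id))
            xs.append(r.positions[:, 0])
            ys.append(r.positions[:, 1])
        if not frames:
            return pd.DataFrame(columns=["frame", "cell_id", "x", "y"])
        df = pd.DataFrame(
            {
                "frame": np.concatenate(frames).astype(int),
                "cell_id": np.concatenate(ids).astype(int),
                "x": np.concatenate(xs),
                "y": np.concatenate(ys),
            }
        )
        return df.sort_values(["frame", "cell_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# fate machinery
# ---------------------------------------------------------------------------


def assign_daughter_fates(profile: KineticProfile, rng: np.random.Generator) -> PairFates:
    """Draw the joint fate of one daughter pair.

    ``SYNC_G0``: both dwells from the prolonged distribution.
    ``SYNC_G1``: both transient with G1-entry times within
    ``sync_delta_max_h`` of each other.  ``ASYNC``: G1-entry times differ by
    ``delta`` from the asynchrony-delta distribution; which daughter lags is
    randomised.  Because synchrony is defined on entry times, the lagging
    daughter's dwell is ``d + delta`` corrected by the difference of the
    siblings' onset draws.  Frequencies converge to ``pair_fate_probs``.
    """
    u = rng.random()
    p0, p1, _ = profile.pair_fate_probs
    o1 = (float(profile.venus_onset_delay.rvs(rng)), float(profile.cherry_onset_delay.rvs(rng)))
    o2 = (float(profile.venus_onset_delay.rvs(rng)), float(profile.cherry_onset_delay.rvs(rng)))
    if u < p0:
        d1 = float(profile.dp_dwell_prolonged.rvs(rng))
        d2 = float(profile.dp_dwell_prolonged.rvs(rng))
        return PairFates("SYNC_G0", d1, d2, None, o1, o2)
    if u < p0 + p1:
        gap = rng.uniform(0.0, profile.sync_delta_max_h)
        delta = None
    else:
        gap = float(profile.async_delta.rvs(rng))
        delta = gap
    d1 = float(profile.dp_dwell_transient.rvs(rng))
    entry1 = sum(o1) + d1
    d2 = max(entry1 + gap - sum(o2), 0.1)
    if rng.random() < 0.5:
        d1, d2 = d2, d1
        o1, o2 = o2, o1
    cat = "SYNC_G1" if delta is None else "ASYNC"
    return PairFates(cat, d1, d2, delta, o1, o2)


def _fate_label(dwell: float, profile: KineticProfile) -> str:
    if dwell > profile.spontaneous_threshold_h:
        return "SPONT_G0"
    if dwell > profile.transient_threshold_h:
        return "TRANSIENT_G0_TO_G1"
    return "DIRECT_G1"


def _founder_dwell(profile: KineticProfile, rng: np.random.Generator) -> tuple[float, bool]:
    """Founder (dwell, prolonged) drawn as one random daughter of a virtual
    pair, so the founder marginal P(dwell > threshold) matches
    ``p_spontaneous_g0``.  ``prolonged`` marks a draw from the prolonged
    distribution: such cells stay double positive through censoring."""
    if profile.founder_p_g0 is not None:
        if rng.random() < profile.founder_p_g0:
            return float(profile.dp_dwell_prolonged.rvs(rng)), True
        return float(profile.dp_dwell_transient.rvs(rng)), False
    pair = assign_daughter_fates(profile, rng)
    dwell = pair.dwell_d1 if rng.random() < 0.5 else pair.dwell_d2
    return float(dwell), pair.category == "SYNC_G0"


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _clip_event(t: Optional[float], end: float) -> Optional[float]:
    if t is None or t >= end:
        return None
    return t


def _simulate_positions(
    records: list["CellRecord"],
    founder_xy: dict[int, np.ndarray],
    spec: MovieSpec,
    profile: KineticProfile,
    rng: np.random.Generator,
) -> None:
    """Frame-synchronous motion with volume exclusion.

    Each cell performs an isotropic Gaussian random walk
    (``motility_sigma`` px/frame) with a short-range pairwise repulsion that
    pushes centroids apart below two spot radii, emulating the physical
    volume exclusion of adherent cells; positions are clamped at the image
    borders.  Daughters start one spot radius from the parent centroid in
    opposite directions along a random axis.
    """
    n_frames = spec.n_frames
    by_id = {r.cell_id: r for r in records}
    margin = 2.0 * spec.psf_sigma
    r_rep = 2.8 * spec.spot_radius  # ~ one cell diameter of clearance
    push = 2.0  # px/frame at full overlap, per neighbour (hard core)

    windows: dict[int, tuple[int, int]] = {}
    starters: dict[int, list[CellRecord]] = {}
    for r in records:
        first, last = r.first_frame, r.first_frame + r.n_frames_alive
        windows[r.cell_id] = (first, last)
        r.positions = np.empty((last - first, 2))
        if last > first:
            starters.setdefault(first, []).append(r)

    def initial_xy(rec: CellRecord) -> np.ndarray:
        """Founder grid position, or parent-derived for daughters (walking
        up through ancestors that divided before the movie started)."""
        if rec.parent_id is None:
            return founder_xy[rec.cell_id].copy()
        parent = by_id[rec.parent_id]
        pf, pl = windows[parent.cell_id]
        base = parent.positions[pl - pf - 1] if pl > pf else initial_xy(parent)
        theta = division_theta.setdefault(rec.parent_id, rng.uniform(0.0, 2.0 * np.pi))
        sgn = 1.0 if parent.cell_id in by_id and _is_first_child(rec, parent) else -1.0
        return base + sgn * spec.spot_radius * np.array([np.cos(theta), np.sin(theta)])

    def _is_first_child(rec: CellRecord, parent: CellRecord) -> bool:
        kids = children.get(parent.cell_id, [])
        return bool(kids) and kids[0] == rec.cell_id

    children: dict[int, list[int]] = {}
    for r in records:
        if r.parent_id is not None:
            children.setdefault(r.parent_id, []).append(r.cell_id)
    division_theta: dict[int, float] = {}

    live: dict[int, np.ndarray] = {}
    sigma = profile.motility_sigma
    for f in range(n_frames):
        # departures
        for cid in [c for c in live if windows[c][1] <= f]:
            del live[cid]
        # motion of existing cells
        for cid in sorted(live):
            step = rng.normal(0.0, sigma, size=2) if sigma > 0 else np.zeros(2)
            live[cid] = live[cid] + step
        # arrivals
        for rec in sorted(starters.get(f, []), key=lambda r: r.cell_id):
            live[rec.cell_id] = initial_xy(rec)
        if not live:
            continue
        # short-range repulsion via a bucket grid (cell size = r_rep)
        ids = sorted(live)
        pos = np.array([live[c] for c in ids])
        buckets: dict[tuple[int, int], list[int]] = {}
        inv = 1.0 / r_rep
        for i, (x, y) in enumerate(pos):
            buckets.setdefault((int(x * inv), int(y * inv)), []).append(i)
        disp = np.zeros_like(pos)
        for (bx, by), members in buckets.items():
            neigh = [
                j
                for dx in (-1, 0, 1)
                for dy in (-1, 0, 1)
                for j in buckets.get((bx + dx, by + dy), ())
            ]
            for i in members:
                for j in neigh:
                    if j <= i:
                        continue
                    d = pos[j] - pos[i]
                    dist = float(np.hypot(*d))
                    if dist >= r_rep:
                        continue
                    if dist < 1e-6:
                        ang = rng.uniform(0.0, 2.0 * np.pi)
                        unit = np.array([np.cos(ang), np.sin(ang)])
                    else:
                        unit = d / dist
                    k = push * (1.0 - dist / r_rep)
                    disp[i] -= k * unit
                    disp[j] += k * unit
        pos = pos + disp
        pos[:, 0] = np.clip(pos[:, 0], margin, spec.width - 1 - margin)
        pos[:, 1] = np.clip(pos[:, 1], margin, spec.height - 1 - margin)
        for i, cid in enumerate(ids):
            live[cid] = pos[i]
            rec = by_id[cid]
            rec.positions[f - rec.first_frame] = pos[i]


def _frame_window(birth: float, end: float, spec: MovieSpec) -> tuple[int, int]:
    """First (inclusive) and last (exclusive) frame index with
    ``birth <= t < end`` for frame times ``t = f * dt``."""
    dt = spec.frame_interval_h
    first = max(0, int(math.ceil(birth / dt - 1e-9)))
    last = min(spec.n_frames, int(math.ceil(end / dt - 1e-9)))
    return first, max(first, last)


def _founder_grid(n: int, spec: MovieSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid founder positions keeping cells away from borders."""
    if n == 0:
        return np.zeros((0, 2))
    margin = 6.0 * spec.psf_sigma
    w = spec.width - 2 * margin
    h = spec.height - 2 * margin
    gx = max(1, int(math.ceil(math.sqrt(n * w / max(h, 1e-9)))))
    gy = int(math.ceil(n / gx))
    xs = margin + (np.arange(gx) + 0.5) * (w / gx)
    ys = margin + (np.arange(gy) + 0.5) * (h / gy)
    grid = np.array([(x, y) for y in ys for x in xs])[:n]
    jitter_scale = 0.15 * min(w / gx, h / gy)
    grid += rng.uniform(-jitter_scale, jitter_scale, size=grid.shape)
    return grid


def simulate_population(
    profile: KineticProfile,
    n_founders: int,
    spec: MovieSpec,
    seed: int,
    with_positions: bool = True,
) -> LineageTree:
    """Simulate a population of ``n_founders`` founder cells and all progeny.

    Founders are laid out on a jittered grid.  In the default
    ``asynchronous`` founder mode each founder is a post-mitotic cell born
    uniformly within ``founder_spread_h`` hours *before* the movie starts, so
    the population is an unsynchronised mix of cycle positions at t = 0.
    The arrest modes model serum-free cohorts seeded from sorted G1 or
    S/G2/M cells.  Identical arguments give bit-identical output.
    """
    if n_founders < 0:
        raise ValueError("n_founders must be >= 0")
    profile.validate()
    rng = np.random.default_rng(seed)
    records: list[CellRecord] = []
    next_id = 0
    duration = spec.duration_h

    def make_record(
        parent_id: Optional[int],
        birth: float,
        dwell: Optional[float],
        *,
        silent: bool = False,
        arrest: bool = False,
        prolonged: bool = False,
        cherry_pre_on: bool = False,
        division_override: Optional[float] = None,
        onsets: Optional[tuple[float, float]] = None,
    ) -> CellRecord:
        """Build one record; appends to ``records`` and schedules daughters."""
        nonlocal next_id
        cid = next_id
        next_id += 1
        if division_override is not None:
            # mid-cycle founder (sgm arrest mode): only the division is
            # observed; a reporter-silent clone still divides
            v_on = c_on = v_off = c_off = None
            division = division_override
            fate = "SILENT" if silent else "CYCLING"
        elif silent:
            v_on = c_on = v_off = c_off = division = None
            fate = "SILENT"
        elif cherry_pre_on:
            # G1-arrest founder: Cherry already on at t=0, Venus rises later
            v_on = birth + float(profile.venus_onset_delay.rvs(rng))
            c_on = birth - profile.cherry_rise_h
            v_off = c_off = division = None
            fate = "SPONT_G0"
        else:
            if onsets is None:
                onsets = (
                    float(profile.venus_onset_delay.rvs(rng)),
                    float(profile.cherry_onset_delay.rvs(rng)),
                )
            v_on = birth + onsets[0]
            c_on = v_on + onsets[1]
            v_off = c_on + dwell
            fate = _fate_label(dwell, profile)
            if arrest or prolonged:
                # starvation daughters and prolonged-G0 cells stay double
                # positive through the end of observation
                v_off = c_off = division = None
                fate = "SPONT_G0"
            else:
                c_off = v_off + float(profile.g1_duration.rvs(rng))
                division = c_off + float(profile.sgm_duration.rvs(rng))
        end = duration
        div_clipped = None
        if division is not None and division < duration:
            div_clipped = division
            end = division
        first, last = _frame_window(birth, end, spec)
        rec = CellRecord(
            cell_id=cid,
            parent_id=parent_id,
            birth_h=birth,
            venus_on_h=_clip_event(v_on, end),
            cherry_on_h=c_on if c_on is not None and c_on < end else None,
            venus_off_h=_clip_event(v_off, end),
            cherry_off_h=_clip_event(c_off, end),
            division_h=div_clipped,
            censored_end_h=duration if div_clipped is None else div_clipped,
            fate=fate,
            dp_dwell_h=dwell,
            first_frame=first,
            n_frames_alive=last - first,
        )
        records.append(rec)
        return rec

    def spawn_daughters(parent: CellRecord) -> None:
        if parent.division_h is None:
            return
        pair = assign_daughter_fates(profile, rng)
        arrest = profile.founder_mode == "sgm_arrest"
        silent = parent.fate == "SILENT"
        for dwell, onsets in ((pair.dwell_d1, pair.onsets_d1), (pair.dwell_d2, pair.onsets_d2)):
            d = make_record(
                parent.cell_id,
                parent.division_h,
                dwell,
                silent=silent,
                arrest=arrest,
                prolonged=pair.category == "SYNC_G0",
                onsets=onsets,
            )
            spawn_daughters(d)

    founder_xy: dict[int, np.ndarray] = {}
    grid = _founder_grid(n_founders, spec, rng)
    for i in range(n_founders):
        xy = grid[i]
        if profile.founder_mode == "g1_arrest":
            silent = rng.random() < profile.p_reporter_silent
            f = make_record(None, 0.0, None, silent=silent, cherry_pre_on=not silent)
            founder_xy[f.cell_id] = xy
        elif profile.founder_mode == "sgm_arrest":
            silent = rng.random() < profile.p_reporter_silent
            division = float(profile.sgm_duration.rvs(rng))
            f = make_record(None, 0.0, None, silent=silent, division_override=division)
            founder_xy[f.cell_id] = xy
            spawn_daughters(f)
        else:
            birth = -rng.uniform(0.0, profile.founder_spread_h)
            if rng.random() < profile.p_reporter_silent:
                f = make_record(None, birth, None, silent=True)
                founder_xy[f.cell_id] = xy
                continue
            dwell, prolonged = _founder_dwell(profile, rng)
            f = make_record(None, birth, dwell, prolonged=prolonged)
            founder_xy[f.cell_id] = xy
            spawn_daughters(f)
    if with_positions:
        _simulate_positions(records, founder_xy, spec, profile, rng)
    return LineageTree(records=records, spec=spec, profile_name=profile.name, seed=seed)


# ---------------------------------------------------------------------------
# reporter kinetics
# ---------------------------------------------------------------------------


def _channel_level(
    t: float,
    on: Optional[float],
    off: Optional[float],
    rise: float,
    fall: float,
) -> float:
    if on is None:
        return 0.0
    up = 1.0 if rise <= 0 else min(max((t - on) / rise, 0.0), 1.0)
    if off is None:
        return up
    down = 1.0 if t <= off else (max(1.0 - (t - off) / fall, 0.0) if fall > 0 else 0.0)
    return min(up, down)


def reporter_level(record: CellRecord, t_h: float, channel: str, profile: KineticProfile) -> float:
    """Deterministic reporter intensity fraction in [0, 1] at time ``t_h``.

    Zero before onset, linear rise to the plateau, linear fall over the
    configured fall duration starting at the off event; a cell whose off
    event is absent (persistent G0) plateaus at 1.
    """
    if not (record.birth_h <= t_h <= record.censored_end_h):
        raise ValueError(
            f"t={t_h} outside cell life [{record.birth_h}, {record.censored_end_h}]"
        )
    if channel == "venus":
        return _channel_level(
            t_h, record.venus_on_h, record.venus_off_h, profile.venus_rise_h, profile.venus_fall_h
        )
    if channel == "cherry":
        return _channel_level(
            t_h,
            record.cherry_on_h,
            record.cherry_off_h,
            profile.cherry_rise_h,
            profile.cherry_fall_h,
        )
    raise ValueError(f"unknown channel {channel!r}")


def trace_arrays_from_record(
    record: CellRecord,
    profile: KineticProfile,
    spec: MovieSpec,
    noise_sigma: float = 0.0,
    basal: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (times, venus, cherry) at the movie frame times the cell is
    alive, in intensity-fraction units, optionally with a basal offset and
    additive Gaussian noise.  Used to emulate extracted traces without
    rendering pixels."""
    frames = record.frames()
    times = frames * spec.frame_interval_h
    venus = np.array([reporter_level(record, t, "venus", profile) for t in times])
    cherry = np.array([reporter_level(record, t, "cherry", profile) for t in times])
    scale = 1.0 - basal
    venus = basal + scale * venus
    cherry = basal + scale * cherry
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        venus = venus + rng.normal(0.0, noise_sigma, size=venus.shape)
        cherry = cherry + rng.normal(0.0, noise_sigma, size=cherry.shape)
    return times, np.clip(venus, 0.0, None), np.clip(cherry, 0.0, None)
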