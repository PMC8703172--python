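"""File formats: multi-page TIFF movies with a metadata sidecar, and the
CSV tables exchanged between pipeline stages.

Movies are 16-bit unsigned multi-page TIFFs, page order frame-major then
channel (channel 0 = Venus, channel 1 = Cherry), written and read with
``tifffile``.  The sidecar is a small YAML file carrying the frame interval
and channel names; it is required downstream because state calls are made in
hours, not frames.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .classification import CellCycleCall
from .lineage import DaughterPairCall

__all__ = [
    "write_movie",
    "read_movie",
    "write_table",
    "read_table",
    "calls_dataframe",
    "calls_from_dataframe",
    "pairs_dataframe",
    "write_summary",
]

CHANNEL_NAMES = ("venus", "cherry")


def _sidecar_path(movie_path: Path) -> Path:
    return movie_path.with_suffix(".meta.yaml")


def write_movie(
    stack: np.ndarray,
    path,
    frame_interval_h: float,
    channel_names: Sequence[str] = CHANNEL_NAMES,
    meta_path=None,
) -> Path:
    """Write a ``(T, 2, H, W)`` uint16 stack and its metadata sidecar."""
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim != 4 or stack.shape[1] != len(channel_names):
        raise ValueError(f"expected (frames, {len(channel_names)}, H, W), got {stack.shape}")
    tifffile.imwrite(path, stack.astype(np.uint16), photometric="minisblack")
    meta = {
        "frame_interval_h": float(frame_interval_h),
        "channels": list(channel_names),
        "n_frames": int(stack.shape[0]),
        "height": int(stack.shape[2]),
        "width": int(stack.shape[3]),
    }
    mp = Path(meta_path) if meta_path is not None else _sidecar_path(path)
    mp.write_text(yaml.safe_dump(meta, sort_keys=False))
    return mp


def read_movie(path, meta_path=None) -> tuple[np.ndarray, dict]:
    """Read a movie stack and its sidecar; returns ``(stack, meta)``.

    Raises ``FileNotFoundError`` with a remedy if the sidecar is missing.
    """
    path = Path(path)
    mp = Path(meta_path) if meta_path is not None else _sidecar_path(path)
    if not mp.exists():
        raise FileNotFoundError(
            f"metadata sidecar {mp} not found; write one with keys "
            "frame_interval_h and channels, or pass meta_path explicitly"
        )
    meta = yaml.safe_load(mp.read_text())
    if "frame_interval_h" not in meta:
        raise KeyError(
            f"{mp} lacks frame_interval_h; add it (hours per frame) to proceed"
        )
    stack = tifffile.imread(path)
    n_ch = len(meta.get("channels", CHANNEL_NAMES))
    if stack.ndim == 3:  # flat page sequence: frame-major then channel
        if stack.shape[0] % n_ch:
            raise ValueError(f"page count {stack.shape[0]} not divisible by {n_ch} channels")
        stack = stack.reshape(stack.shape[0] // n_ch, n_ch, *stack.shape[1:])
    return stack, meta


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


_CALL_COLUMNS = [
    "track_id",
    "classifiable",
    "reason",
    "dp_duration_h",
    "dp_start_h",
    "spontaneous_g0",
    "transient_g0",
    "g1_entry_h",
    "g1_entry_mid_h",
    "g1_exit_h",
    "censored_dp",
    "trace_end_h",
    "order_violations",
]


def calls_dataframe(calls: Sequence[CellCycleCall]) -> pd.DataFrame:
    rows = [
        (
            c.track_id,
            c.classifiable,
            c.reason,
            c.dp_duration_h,
            c.dp_start_h,
            c.spontaneous_g0,
            c.transient_g0,
            c.g1_entry_h,
            c.g1_entry_mid_h,
            c.g1_exit_h,
            c.censored_dp,
            c.trace_end_h,
            ";".join(c.order_violations),
        )
        for c in calls
    ]
    return pd.DataFrame(rows, columns=_CALL_COLUMNS)


def _opt_float(v) -> Optional[float]:
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)


def _opt_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return bool(v)


def calls_from_dataframe(df: pd.DataFrame) -> list[CellCycleCall]:
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            CellCycleCall(
                track_id=int(row.track_id),
                classifiable=bool(row.classifiable),
                reason="" if pd.isna(row.reason) else str(row.reason),
                dp_duration_h=_opt_float(row.dp_duration_h),
                dp_start_h=_opt_float(row.dp_start_h),
                spontaneous_g0=_opt_bool(row.spontaneous_g0),
                transient_g0=_opt_bool(row.transient_g0),
                g1_entry_h=_opt_float(row.g1_entry_h),
                g1_entry_mid_h=_opt_float(row.g1_entry_mid_h),
                g1_exit_h=_opt_float(row.g1_exit_h),
                censored_dp=bool(row.censored_dp),
                trace_end_h=_opt_float(row.trace_end_h),
                order_violations=(
                    [] if pd.isna(row.order_violations) or not row.order_violations
                    else str(row.order_violations).split(";")
                ),
            )
        )
    return calls


def pairs_dataframe(pairs: Sequence[DaughterPairCall]) -> pd.DataFrame:
    rows = [
        (p.parent_track_id, p.category, p.delta_g1_entry_h, p.division_time_h, p.censored_delta)
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "parent_track_id",
            "category",
            "delta_g1_entry_h",
            "division_time_h",
            "censored_delta",
        ],
    )


def write_summary(summary_dict: dict, path_prefix) -> tuple[Path, Path]:
    """Write a summary as human-readable YAML and machine-readable JSON."""
    prefix = Path(path_prefix)
    ypath = prefix.with_suffix(".yaml")
    jpath = prefix.with_suffix(".json")
    ypath.write_text(yaml.safe_dump(summary_dict, sort_keys=False))
    jpath.write_text(json.dumps(summary_dict, indent=2, default=float))
    return ypath, jpath
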