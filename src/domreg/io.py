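"""Tracking and pass-event CSV input/output.

Tracking files are long-format CSVs with columns
``frame, time_s, player_id, team, x_m, y_m``; event files have
``pass_frame, reception_frame, passer_id, receiver_id, success``.
Positions outside the pitch rectangle are clamped to its boundary (and
counted) rather than dropped so trajectories stay contiguous; rows with
non-finite coordinates are rejected with a count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import PitchConfig

__all__ = [
    "TrackingDataset",
    "PassEvent",
    "FormatError",
    "IntegrityError",
    "read_tracking",
    "write_tracking",
    "read_events",
    "write_events",
]

TRACKING_COLUMNS = ["frame", "time_s", "player_id", "team", "x_m", "y_m"]
EVENT_COLUMNS = ["pass_frame", "reception_frame", "passer_id", "receiver_id", "success"]


class FormatError(ValueError):
    """A file does not match the expected CSV schema."""


class IntegrityError(ValueError):
    """A file parses but violates a dataset invariant."""


@dataclass(frozen=True)
class PassEvent:
    """A completed (or attempted) pass: ball release and reception frames."""

    pass_frame: int
    reception_frame: int
    passer_id: str
    receiver_id: str
    success: bool = True

    def window_s(self, frame_rate: float) -> float:
        """Time from release to reception, seconds."""
        return (self.reception_frame - self.pass_frame) / frame_rate

    def __post_init__(self) -> None:
        if self.reception_frame <= self.pass_frame:
            raise ValueError("reception_frame must be > pass_frame")


@dataclass
class TrackingDataset:
    """Frame-indexed 2-D positions for a roster of players.

    ``data`` is a long-format DataFrame with the tracking columns, sorted by
    (player_id, frame).  Rosters may vary per frame; per-player frame gaps
    are permitted but flagged in ``gap_players``.
    """

    data: pd.DataFrame
    config: PitchConfig = field(default_factory=PitchConfig)
    n_clamped: int = 0
    n_rejected: int = 0
    gap_players: tuple = ()

    def __post_init__(self) -> None:
        missing = [c for c in TRACKING_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"tracking data missing column(s): {', '.join(missing)}")
        self.data = self.data[TRACKING_COLUMNS].sort_values(
            ["player_id", "frame"], kind="mergesort"
        )
        self.data.reset_index(drop=True, inplace=True)

    @property
    def players(self) -> list:
        return sorted(self.data["player_id"].unique().tolist())

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.data["frame"].unique())

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def team_of(self, player_id) -> str:
        sub = self.data.loc[self.data["player_id"] == player_id, "team"]
        if sub.empty:
            raise KeyError(player_id)
        return sub.iloc[0]

    def player_frame(self, player_id) -> pd.DataFrame:
        sub = self.data[self.data["player_id"] == player_id]
        if sub.empty:
            raise KeyError(player_id)
        return sub

    def positions_at(self, frame: int) -> pd.DataFrame:
        """All player positions at one frame (player_id, team, x_m, y_m)."""
        sub = self.data[self.data["frame"] == frame]
        return sub[["player_id", "team", "x_m", "y_m"]].reset_index(drop=True)


def _clamp_positions(df: pd.DataFrame, config: PitchConfig) -> tuple[pd.DataFrame, int]:
    x = df["x_m"].to_numpy(float)
    y = df["y_m"].to_numpy(float)
    xc = np.clip(x, 0.0, config.length_x)
    yc = np.clip(y, 0.0, config.width_y)
    n_clamped = int(np.count_nonzero((xc != x) | (yc != y)))
    if n_clamped:
        df = df.copy()
        df["x_m"] = xc
        df["y_m"] = yc
    return df, n_clamped


def _check_monotone_frames(df: pd.DataFrame) -> list:
    gaps = []
    for pid, sub in df.groupby("player_id", sort=False):
        f = sub["frame"].to_numpy()
        d = np.diff(f)
        if np.any(d <= 0):
            raise IntegrityError(
                f"frames for player {pid!r} are not strictly increasing"
            )
        if np.any(d > 1):
            gaps.append(pid)
    return gaps


def read_tracking(path: str | Path, config: PitchConfig | None = None) -> TrackingDataset:
    """Read and validate a tracking CSV.

    Non-finite rows are dropped (counted in ``n_rejected``); out-of-pitch
    positions are clamped to the boundary (counted in ``n_clamped``).
    """
    config = config or PitchConfig()
    df = pd.read_csv(path)
    missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    df = df[TRACKING_COLUMNS].copy()
    df["player_id"] = df["player_id"].astype(str)
    df["team"] = df["team"].astype(str)
    finite = np.isfinite(df["x_m"]) & np.isfinite(df["y_m"]) & np.isfinite(df["time_s"])
    n_rejected = int((~finite).sum())
    if n_rejected:
        warnings.warn(f"{path}: rejected {n_rejected} row(s) with non-finite values")
        df = df[finite]
    # monotonicity is a property of the file, so check before sorting
    gaps = _check_monotone_frames(df)
    df = df.sort_values(["player_id", "frame"], kind="mergesort")
    df, n_clamped = _clamp_positions(df, config)
    return TrackingDataset(
        data=df.reset_index(drop=True),
        config=config,
        n_clamped=n_clamped,
        n_rejected=n_rejected,
        gap_players=tuple(gaps),
    )


def write_tracking(dataset: TrackingDataset, path: str | Path) -> None:
    dataset.data.to_csv(path, index=False, float_format="%.6f")


def read_events(
    path: str | Path,
    frame_rate: float = 30.0,
    include_failed: bool = False,
) -> list[PassEvent]:
    """Read a pass-event CSV, keeping successful passes only by default.

    Rows whose reception frame is not after the pass frame are rejected
    with a warning; an empty file yields an empty list.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    events: list[PassEvent] = []
    n_bad = 0
    for row in df.itertuples(index=False):
        success = bool(row.success)
        if not success and not include_failed:
            continue
        if row.reception_frame <= row.pass_frame:
            n_bad += 1
            continue
        events.append(
            PassEvent(
                pass_frame=int(row.pass_frame),
                reception_frame=int(row.reception_frame),
                passer_id=str(row.passer_id),
                receiver_id=str(row.receiver_id),
                success=success,
            )
        )
    if n_bad:
        warnings.warn(f"{path}: rejected {n_bad} event(s) with reception <= pass frame")
    return events


def write_events(events: Iterable[PassEvent], path: str | Path) -> None:
    rows = [
        {
            "pass_frame": e.pass_frame,
            "reception_frame": e.reception_frame,
            "passer_id": e.passer_id,
            "receiver_id": e.receiver_id,
            "success": e.success,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)
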