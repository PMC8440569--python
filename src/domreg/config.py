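"""Pitch geometry, raster layout and model hyper-parameters.

The pitch is modelled as the rectangle [0, length_x] x [0, width_y] in metres,
origin at a corner, x along the 105 m touchline and y along the 68 m goal
line.  The probability raster divides it into half-open square cells
[k*cell_size, (k+1)*cell_size), so every on-pitch point maps to exactly one
cell; rows index y and columns index x.  At the defaults this gives a
680-row by 1050-column grid of 0.01 m^2 cells.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["PitchConfig", "ModelConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PitchConfig:
    """Pitch rectangle and raster resolution.

    Parameters
    ----------
    length_x : float
        Pitch length along x, metres (default 105).
    width_y : float
        Pitch width along y, metres (default 68).
    cell_size : float
        Raster cell edge, metres (default 0.1).  ``length_x`` and
        ``width_y`` must be integer multiples of it.
    frame_rate : float
        Tracking sampling rate, Hz (default 30).
    """

    length_x: float = 105.0
    width_y: float = 68.0
    cell_size: float = 0.1
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        for name in ("length_x", "width_y", "cell_size", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("length_x", "width_y"):
            ratio = getattr(self, name) / self.cell_size
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"{name}={getattr(self, name)} is not an integer multiple "
                    f"of cell_size={self.cell_size}"
                )

    @property
    def n_rows(self) -> int:
        return round(self.width_y / self.cell_size)

    @property
    def n_cols(self) -> int:
        return round(self.length_x / self.cell_size)

    @property
    def cell_area(self) -> float:
        """Cell area A in m^2 (0.01 at defaults)."""
        return self.cell_size * self.cell_size

    @property
    def pitch_area(self) -> float:
        return self.length_x * self.width_y

    def grid_shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map metre coordinates to (row, col) indices (may be out of range)."""
        col = np.floor(np.asarray(x, dtype=float) / self.cell_size).astype(np.int64)
        row = np.floor(np.asarray(y, dtype=float) / self.cell_size).astype(np.int64)
        return row, col

    def on_pitch_cells(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of the movement/probability model.

    speed_edges / accel_edges define the half-open (v, a) bin matrix the
    movement models live in: speeds 0..10 m/s and accelerations -6..6 m/s^2
    in unit steps.  Values beyond the outer edges clamp into the nearest
    edge bin so sprints are not silently discarded.
    """

    horizon_s: float = 3.0
    speed_min: float = 0.0
    speed_max: float = 10.0
    speed_step: float = 1.0
    accel_min: float = -6.0
    accel_max: float = 6.0
    accel_step: float = 1.0
    sigma_cells: float = 20.0          # Gaussian smoothing sd, in grid cells
    threshold: float = 0.001           # values strictly below are zeroed
    min_samples: int = 200             # per-cell floor (post-mirroring)
    max_segments_per_cell: int | None = 2000  # deterministic cap pre-mirroring
    cutoff_hz: float = 0.4             # Butterworth low-pass cut-off
    filter_order: int = 3
    stillness_floor: float = 1e-4      # m per frame; below it theta_d is masked
    cumulative: bool = True            # horizon T = union of lags <= T
    normalization: str = "density"     # or "unit-max"
    truncate_sigmas: float = 4.0       # Gaussian kernel truncation radius

    def __post_init__(self) -> None:
        if self.horizon_s <= 0:
            raise ValueError("horizon_s must be > 0")
        if self.normalization not in ("unit-max", "density"):
            raise ValueError("normalization must be 'unit-max' or 'density'")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")

    @property
    def speed_edges(self) -> np.ndarray:
        n = round((self.speed_max - self.speed_min) / self.speed_step)
        return self.speed_min + self.speed_step * np.arange(n + 1)

    @property
    def accel_edges(self) -> np.ndarray:
        n = round((self.accel_max - self.accel_min) / self.accel_step)
        return self.accel_min + self.accel_step * np.arange(n + 1)

    @property
    def n_speed_bins(self) -> int:
        return len(self.speed_edges) - 1

    @property
    def n_accel_bins(self) -> int:
        return len(self.accel_edges) - 1

    def bin_of(self, v: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Half-open (v, a) bin indices with clamping into the edge bins."""
        vi = np.floor((np.asarray(v, float) - self.speed_min) / self.speed_step)
        ai = np.floor((np.asarray(a, float) - self.accel_min) / self.accel_step)
        vi = np.clip(vi, 0, self.n_speed_bins - 1).astype(np.int64)
        ai = np.clip(ai, 0, self.n_accel_bins - 1).astype(np.int64)
        return vi, ai

    def horizon_frames(self, frame_rate: float, horizon_s: float | None = None) -> int:
        h = self.horizon_s if horizon_s is None else horizon_s
        n = h * frame_rate
        n_int = int(round(n))
        if abs(n - n_int) > 1e-9:
            raise ValueError(
                f"horizon {h} s is not an integer number of frames at {frame_rate} Hz"
            )
        if n_int < 1:
            raise ValueError("horizon shorter than one frame")
        return n_int


def _to_dict(cfg: Any) -> dict:
    return dataclasses.asdict(cfg)


def config_hash(pitch: PitchConfig, model: ModelConfig) -> str:
    payload = json.dumps(
        {"pitch": _to_dict(pitch), "model": _to_dict(model)}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def save_config(path: str | Path, pitch: PitchConfig, model: ModelConfig) -> None:
    payload = {"pitch": _to_dict(pitch), "model": _to_dict(model)}
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_config(path: str | Path) -> tuple[PitchConfig, ModelConfig]:
    """Read a JSON or YAML config file written by :func:`save_config`."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return PitchConfig(**payload.get("pitch", {})), ModelConfig(**payload.get("model", {}))
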