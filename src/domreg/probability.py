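"""Reach-probability grids: histogram density, smoothing, thresholding.

A movement model placed at a player's instantaneous state becomes a
pitch-wide raster of reach values:

1. the model's canonical samples for lags up to the horizon are rotated
   back to the player's displacement direction and translated to the
   player's position (point operations, so no raster interpolation error);
2. a 2-D histogram with probability-density normalisation assigns each
   0.01 m^2 cell the value pr = c / (N * A), where c is the in-cell count,
   N the total sample count (off-pitch samples included) and A the cell
   area — on-pitch mass then sums to <= 1;
3. an isotropic Gaussian filter (sigma = 20 cells = 2 m by default,
   kernel truncated at 4 sigma, zero padding beyond the pitch) spreads the
   discrete histogram into a spatially coherent field;
4. values strictly below the 0.001 floor are set to zero, so regions of
   negligible reachability never enter the dominance comparison.  In the
   default "density" mode the floor applies to the smoothed densities
   themselves (units 1/m^2), which keeps values comparable across players;
   "unit-max" mode first rescales each grid to [0, 1] by its maximum.

Internally the pipeline runs on a local window just covering the sample
support plus the kernel's truncation radius; because the truncated kernel
is exactly zero beyond that radius, the embedded full-pitch grid is
identical to one computed on the full raster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import ModelConfig, PitchConfig
from .movement import ModelLibrary, _rotate, rotation_angle

__all__ = [
    "ProbabilityGrid",
    "PlayerState",
    "histogram_pdf",
    "smooth",
    "normalize_and_threshold",
    "player_probability",
]


@dataclass
class ProbabilityGrid:
    """Raster of non-negative reach values for one player at one frame."""

    values: np.ndarray
    config: PitchConfig
    player_id: str | None = None
    frame: int | None = None
    horizon_s: float | None = None
    mode: str = "density"

    def __post_init__(self) -> None:
        if self.values.shape != self.config.grid_shape():
            raise ValueError(
                f"grid shape {self.values.shape} != expected {self.config.grid_shape()}"
            )

    @property
    def mass(self) -> float:
        """Total probability mass sum(pr) * A (<= 1 in density mode)."""
        return float(self.values.sum() * self.config.cell_area)

    def value_at(self, x: float, y: float) -> float:
        row, col = self.config.cell_of(x, y)
        if not self.config.on_pitch_cells(row, col):
            raise ValueError(f"({x}, {y}) is off the pitch raster")
        return float(self.values[int(row), int(col)])


@dataclass(frozen=True)
class PlayerState:
    """Instantaneous kinematic state used to place a movement model."""

    position: tuple[float, float]
    theta_d: float
    v: float
    a: float
    frame: int | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.position).all() and np.isfinite(self.theta_d)):
            raise ValueError("state requires finite position and theta_d")
        if self.v < 0:
            raise ValueError("speed must be >= 0")


@dataclass
class _LocalGrid:
    """Dense values on a sub-rectangle of the raster; zero elsewhere."""

    row0: int
    col0: int
    values: np.ndarray  # (h, w)
    n_total: int        # N of the density normalisation

    def embed(self, config: PitchConfig) -> np.ndarray:
        full = np.zeros(config.grid_shape())
        h, w = self.values.shape
        full[self.row0 : self.row0 + h, self.col0 : self.col0 + w] = self.values
        return full

    def value_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        h, w = self.values.shape
        r = rows - self.row0
        c = cols - self.col0
        inside = (r >= 0) & (r < h) & (c >= 0) & (c < w)
        out = np.zeros(np.shape(rows), dtype=float)
        if np.any(inside):
            out[inside] = self.values[r[inside], c[inside]]
        return out


def _local_pipeline(
    points: np.ndarray,
    config: PitchConfig,
    model_config: ModelConfig,
    mode: str,
) -> _LocalGrid:
    """Histogram -> smooth -> normalise/threshold on a support-fitting window."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n_total = points.shape[0]
    margin = int(math.ceil(model_config.truncate_sigmas * model_config.sigma_cells)) + 1
    rows, cols = config.cell_of(points[:, 0], points[:, 1])
    on = config.on_pitch_cells(rows, cols)
    rows, cols = rows[on], cols[on]
    if rows.size == 0 or n_total == 0:
        return _LocalGrid(row0=0, col0=0, values=np.zeros((1, 1)), n_total=n_total)
    r0 = max(0, int(rows.min()) - margin)
    r1 = min(config.n_rows, int(rows.max()) + margin + 1)
    c0 = max(0, int(cols.min()) - margin)
    c1 = min(config.n_cols, int(cols.max()) + margin + 1)
    h, w = r1 - r0, c1 - c0
    flat = (rows - r0) * w + (cols - c0)
    counts = np.bincount(flat, minlength=h * w).reshape(h, w).astype(float)
    dens = counts / (n_total * config.cell_area)
    smoothed = gaussian_filter(
        dens,
        sigma=model_config.sigma_cells,
        mode="constant",
        cval=0.0,
        truncate=model_config.truncate_sigmas,
    )
    if mode == "unit-max":
        m = smoothed.max()
        if m > 0:
            smoothed = smoothed / m
    smoothed[smoothed < model_config.threshold] = 0.0
    return _LocalGrid(row0=r0, col0=c0, values=smoothed, n_total=n_total)


def histogram_pdf(
    points: np.ndarray, config: PitchConfig | None = None
) -> ProbabilityGrid:
    """Density-normalised 2-D histogram of sample points on the pitch raster.

    Each cell gets c / (N * A); off-pitch points count toward N but land in
    no cell, so the on-pitch mass is N_on / N.  An empty point set yields an
    all-zero grid.
    """
    config = config or PitchConfig()
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n_total = points.shape[0]
    values = np.zeros(config.grid_shape())
    if n_total:
        rows, cols = config.cell_of(points[:, 0], points[:, 1])
        on = config.on_pitch_cells(rows, cols)
        np.add.at(values, (rows[on], cols[on]), 1.0)
        values /= n_total * config.cell_area
    return ProbabilityGrid(values=values, config=config, mode="density")


def smooth(grid: ProbabilityGrid, sigma_cells: float = 20.0,
           truncate: float = 4.0) -> ProbabilityGrid:
    """Isotropic Gaussian smoothing with zero padding beyond the pitch.

    Zero (not reflective) padding is deliberate: reflection would fabricate
    reach beyond the touchline, whereas letting mass leak off-pitch mirrors
    the histogram's own off-pitch drop.
    """
    values = gaussian_filter(
        grid.values, sigma=sigma_cells, mode="constant", cval=0.0, truncate=truncate
    )
    return ProbabilityGrid(
        values=values, config=grid.config, player_id=grid.player_id,
        frame=grid.frame, horizon_s=grid.horizon_s, mode=grid.mode,
    )


def normalize_and_threshold(
    grid: ProbabilityGrid, threshold: float = 0.001, mode: str = "unit-max"
) -> ProbabilityGrid:
    """Scale to [0, 1] by the grid maximum (unit-max mode) and zero values
    strictly below the threshold.

    In density mode the raw densities are thresholded directly.  All-zero
    grids pass through unchanged; a value exactly at the threshold survives.
    """
    if mode not in ("unit-max", "density"):
        raise ValueError("mode must be 'unit-max' or 'density'")
    values = grid.values.copy()
    if mode == "unit-max":
        m = values.max()
        if m > 0:
            values /= m
    values[values < threshold] = 0.0
    return ProbabilityGrid(
        values=values, config=grid.config, player_id=grid.player_id,
        frame=grid.frame, horizon_s=grid.horizon_s, mode=mode,
    )


def _placed_points(
    library: ModelLibrary, state: PlayerState, horizon_s: float
) -> np.ndarray:
    """Model samples for the state, rotated/translated onto the pitch."""
    cfg = library.model_config
    fr = library.pitch_config.frame_rate
    L = cfg.horizon_frames(fr, horizon_s)
    if L > library.horizon_frames:
        raise ValueError(
            f"horizon {horizon_s} s exceeds library horizon "
            f"{library.horizon_frames / fr} s"
        )
    model = library.lookup(state.v, state.a)
    canonical = (
        model.points_up_to(L) if cfg.cumulative else model.points_at(L)
    ).astype(float)
    placed = _rotate(canonical, -rotation_angle(state.theta_d))
    placed[:, 0] += state.position[0]
    placed[:, 1] += state.position[1]
    return placed


def _player_local(
    library: ModelLibrary, state: PlayerState, horizon_s: float, mode: str | None = None
) -> _LocalGrid:
    mode = mode or library.model_config.normalization
    points = _placed_points(library, state, horizon_s)
    return _local_pipeline(points, library.pitch_config, library.model_config, mode)


def player_probability(
    library: ModelLibrary,
    state: PlayerState,
    horizon_s: float | None = None,
    mode: str | None = None,
    player_id: str | None = None,
) -> ProbabilityGrid:
    """Full reach-probability grid for one player state.

    Selects the movement model for (state.v, state.a) (nearest populated
    bin if that cell is empty), takes the union of canonical samples for
    lags up to the horizon, rotates them to the player's displacement
    direction, translates to the player's position, and runs the
    histogram -> smooth -> normalise/threshold pipeline.  Deterministic
    for fixed inputs.
    """
    cfg = library.model_config
    horizon_s = cfg.horizon_s if horizon_s is None else horizon_s
    mode = mode or cfg.normalization
    local = _player_local(library, state, horizon_s, mode=mode)
    return ProbabilityGrid(
        values=local.embed(library.pitch_config),
        config=library.pitch_config,
        player_id=player_id,
        frame=state.frame,
        horizon_s=horizon_s,
        mode=mode,
    )
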