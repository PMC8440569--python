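"""Per-cell dominance resolution and region areas.

For each raster cell, the dominant player is the one with the strictly
greatest reach probability; cells where every player's value is zero are
free space (label 0).  Ties among positive maxima are broken
deterministically toward the lowest player identifier and counted.  Maps
are per-frame — there is no temporal smoothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .config import PitchConfig
from .probability import ProbabilityGrid, _LocalGrid

__all__ = ["DominanceMap", "AreaReport", "FREE", "compute_dominance", "region_areas"]

FREE = 0  # label of cells no player controls


@dataclass
class DominanceMap:
    """Integer raster of per-cell owners; 0 = free space.

    ``players`` maps label k (k >= 1) to the player id ``players[k - 1]``;
    labels are assigned in ascending player-id order.
    """

    labels: np.ndarray
    players: list
    config: PitchConfig
    frame: int | None = None
    horizon_s: float | None = None
    tie_count: int = 0

    def label_of(self, player_id) -> int:
        return self.players.index(player_id) + 1

    def owner_at(self, x: float, y: float):
        """Player id dominating the cell containing (x, y), or None if free."""
        row, col = self.config.cell_of(x, y)
        if not self.config.on_pitch_cells(row, col):
            raise ValueError(f"({x}, {y}) is off the pitch raster")
        lab = int(self.labels[int(row), int(col)])
        return None if lab == FREE else self.players[lab - 1]

    def legend(self) -> dict:
        return {"FREE": FREE, **{str(p): i + 1 for i, p in enumerate(self.players)}}

    def save(self, path) -> None:
        """Compressed integer raster plus a JSON legend sidecar."""
        np.savez_compressed(
            path,
            labels=self.labels.astype(np.int32),
            legend=json.dumps(
                {
                    "players": [str(p) for p in self.players],
                    "FREE": FREE,
                    "frame": self.frame,
                    "horizon_s": self.horizon_s,
                    "tie_count": self.tie_count,
                }
            ),
        )


@dataclass
class AreaReport:
    """Dominant-region and free-space areas (m^2) for one frame."""

    player_areas: dict
    free_area: float
    frame: int | None = None

    @property
    def total_area(self) -> float:
        return float(sum(self.player_areas.values()) + self.free_area)


def _stack_sorted(grids: list[ProbabilityGrid]) -> tuple[np.ndarray, list]:
    ids = [g.player_id for g in grids]
    if any(i is None for i in ids):
        raise ValueError("every grid needs a player_id for dominance")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate player_id among grids")
    order = np.argsort(np.asarray(ids, dtype=object))
    players = [ids[i] for i in order]
    stack = np.stack([grids[i].values for i in order], axis=0)
    return stack, players


def compute_dominance(grids: list[ProbabilityGrid]) -> DominanceMap:
    """Resolve per-cell dominance across players of one frame.

    All grids must share shape, frame, horizon and normalisation mode
    (values under different normalisations are incomparable).  The owner of
    a cell is the player with the strictly greatest value; ties among
    positive maxima go to the lowest player id and are counted; all-zero
    cells are free.
    """
    if not grids:
        raise ValueError("need at least one probability grid")
    modes = {g.mode for g in grids}
    if len(modes) > 1:
        raise ValueError(f"mixed normalization modes are incomparable: {modes}")
    for attr in ("frame", "horizon_s"):
        vals = {getattr(g, attr) for g in grids}
        if len(vals) > 1:
            raise ValueError(f"grids disagree on {attr}: {vals}")
    shapes = {g.values.shape for g in grids}
    if len(shapes) > 1:
        raise ValueError(f"grids disagree on shape: {shapes}")

    stack, players = _stack_sorted(grids)
    best = stack.max(axis=0)
    # argmax returns the first (lowest-id) maximiser, giving the tie rule for free
    owner = stack.argmax(axis=0).astype(np.int32) + 1
    owner[best <= 0.0] = FREE
    positive = best > 0.0
    tie_count = int(((stack == best[None]).sum(axis=0) > 1)[positive].sum())
    return DominanceMap(
        labels=owner,
        players=players,
        config=grids[0].config,
        frame=grids[0].frame,
        horizon_s=grids[0].horizon_s,
        tie_count=tie_count,
    )


def _dominance_from_locals(
    locals_by_player: dict,
    config: PitchConfig,
    frame: int | None = None,
    horizon_s: float | None = None,
) -> DominanceMap:
    """Dominance map assembled from per-player local windows.

    Equivalent to :func:`compute_dominance` on the embedded full grids, but
    touches only each player's support window.  Sweeping players in
    ascending id order with a strict ``>`` update reproduces the
    lowest-id tie rule.
    """
    players = sorted(locals_by_player)
    best = np.zeros(config.grid_shape())
    labels = np.zeros(config.grid_shape(), dtype=np.int32)
    tie_count = 0
    for k, pid in enumerate(players, start=1):
        loc: _LocalGrid = locals_by_player[pid]
        h, w = loc.values.shape
        sl = (slice(loc.row0, loc.row0 + h), slice(loc.col0, loc.col0 + w))
        window_best = best[sl]
        pos = loc.values > 0.0
        tie_count += int(np.count_nonzero(pos & (loc.values == window_best)))
        better = loc.values > window_best
        window_best[better] = loc.values[better]
        labels[sl][better] = k
    return DominanceMap(
        labels=labels,
        players=players,
        config=config,
        frame=frame,
        horizon_s=horizon_s,
        tie_count=tie_count,
    )


def region_areas(dmap: DominanceMap, config: PitchConfig | None = None) -> AreaReport:
    """Cell-count areas per player plus free space; conserves the pitch area."""
    config = config or dmap.config
    counts = np.bincount(dmap.labels.ravel(), minlength=len(dmap.players) + 1)
    A = config.cell_area
    return AreaReport(
        player_areas={
            pid: float(counts[i + 1] * A) for i, pid in enumerate(dmap.players)
        },
        free_area=float(counts[FREE] * A),
        frame=dmap.frame,
    )
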