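"""Nearest-point Voronoi regions clipped to the pitch — the classical,
capacity-blind dominant-region baseline.

Every pitch point belongs to the nearest player, so the tessellation
covers the rectangle exactly and leaves no free space — the structural
contrast with the probabilistic dominance maps.  Polygon areas are
computed geometrically (not by raster counting) to keep the area
comparison free of discretisation bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, box

from .config import PitchConfig

__all__ = ["VoronoiReport", "voronoi_regions"]


@dataclass
class VoronoiReport:
    """Per-player clipped Voronoi polygons and their areas for one frame."""

    polygons: dict          # player_id -> shapely Polygon (clipped to pitch)
    areas: dict             # player_id -> m^2
    frame: int | None = None

    @property
    def total_area(self) -> float:
        return float(sum(self.areas.values()))

    def vertices(self, player_id) -> np.ndarray:
        return np.asarray(self.polygons[player_id].exterior.coords)


def voronoi_regions(
    positions: dict,
    config: PitchConfig | None = None,
    frame: int | None = None,
) -> VoronoiReport:
    """Voronoi tessellation of the pitch for a set of player positions.

    ``positions`` maps player_id -> (x, y) in metres, all inside the pitch.
    Coincident positions are perturbed by 1e-9 m (with a warning) so the
    tessellation is well defined.  Unbounded outer cells are clipped to the
    pitch rectangle; areas sum to the pitch area up to floating error.
    """
    config = config or PitchConfig()
    if not positions:
        raise ValueError("need at least one player position")
    players = sorted(positions)
    pts = np.array([positions[p] for p in players], dtype=float)
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > config.length_x) or \
       np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > config.width_y):
        raise ValueError("all positions must lie inside the pitch rectangle")

    # perturb exact duplicates so every generator has its own cell
    seen: dict[tuple, int] = {}
    for i in range(len(pts)):
        key = (pts[i, 0], pts[i, 1])
        while key in seen:
            warnings.warn(
                f"duplicate position {key} for player {players[i]!r}; "
                "perturbing by 1e-9 m"
            )
            pts[i, 0] += 1e-9
            pts[i, 1] += 1e-9
            key = (pts[i, 0], pts[i, 1])
        seen[key] = i

    pitch = box(0.0, 0.0, config.length_x, config.width_y)
    if len(players) == 1:
        polys = {players[0]: pitch}
    else:
        cells = shapely.voronoi_polygons(MultiPoint(pts), extend_to=pitch)
        polys = {}
        remaining = list(cells.geoms)
        for pid, (x, y) in zip(players, pts):
            p = Point(x, y)
            idx = min(range(len(remaining)), key=lambda k: remaining[k].distance(p))
            polys[pid] = remaining.pop(idx).intersection(pitch)
    areas = {pid: float(poly.area) for pid, poly in polys.items()}
    return VoronoiReport(polygons=polys, areas=areas, frame=frame)
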