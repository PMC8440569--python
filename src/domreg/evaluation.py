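"""Evaluation protocols: prediction accuracy at time lags, the pass
time-window distribution, and the model-vs-Voronoi area comparison.

Accuracy: at every evaluated frame t, a dominance map is built at horizon
T and a player scores a hit iff the raster cell holding their real
position at t + T is labelled theirs.  Free cells and cells owned by
another player both count as misses.  Percent correct is reported per
player, with the across-player mean, standard deviation and a t-based 95%
confidence interval per horizon.

Pass windows: percentiles (linear interpolation) of release-to-reception
times of successful passes, plus the implied model horizon (95th
percentile rounded up to the nearest 0.5 s).

Area comparison: medians and interquartile ranges of player-frame areas,
bootstrap confidence intervals for the medians, a two-sided Wilcoxon
rank-sum test (exact enumeration at small n, normal approximation
otherwise) and the Rosenthal effect size r = |Z| / sqrt(N) with Cohen's
qualitative labels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import ModelConfig, PitchConfig
from .dominance import _dominance_from_locals, region_areas
from .io import PassEvent, TrackingDataset
from .kinematics import Trajectory, compute_kinematics, smooth_trajectory
from .movement import ModelLibrary, _rotate, rotation_angle
from .probability import _local_pipeline
from .voronoi import voronoi_regions

__all__ = [
    "AccuracyReport",
    "WindowReport",
    "AreaComparison",
    "AreaProtocolResult",
    "accuracy",
    "pass_windows",
    "compare_areas",
    "area_protocol",
    "evaluate_match",
]


@dataclass
class AccuracyReport:
    """Percent correct dominant-region predictions per player and horizon."""

    horizons: tuple
    per_player: dict            # pid -> {T: percent}
    evaluated: dict             # pid -> {T: frames in the denominator}

    def percents(self, horizon: float) -> np.ndarray:
        vals = [
            self.per_player[p][horizon]
            for p in sorted(self.per_player)
            if self.evaluated[p][horizon] > 0
        ]
        return np.asarray(vals, dtype=float)

    def summary(self) -> dict:
        """Across-player mean, sd and t-based 95% CI per horizon."""
        out = {}
        for T in self.horizons:
            vals = self.percents(T)
            n = len(vals)
            mean = float(vals.mean()) if n else math.nan
            sd = float(vals.std(ddof=1)) if n > 1 else math.nan
            if n > 1:
                half = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
                ci = (mean - half, mean + half)
            else:
                ci = (math.nan, math.nan)
            out[T] = {"mean": mean, "sd": sd, "ci95": ci, "n_players": n}
        return out


@dataclass
class WindowReport:
    """Distribution of pass release-to-reception windows, seconds."""

    n: int
    p25: float
    p50: float
    p75: float
    p95: float
    recommended_horizon_s: float


@dataclass
class AreaComparison:
    """Model-vs-Voronoi player-frame area statistics."""

    model_median: float
    model_iqr: float
    model_p25: float
    model_p75: float
    model_ci95: tuple
    voronoi_median: float
    voronoi_iqr: float
    voronoi_p25: float
    voronoi_p75: float
    voronoi_ci95: tuple
    p_value: float
    z: float
    r: float
    label: str
    n_model: int
    n_voronoi: int


@dataclass
class AreaProtocolResult:
    """Per-player-frame areas collected on a shared set of frames."""

    model_areas: np.ndarray     # player-frame dominant-region areas, m^2
    voronoi_areas: np.ndarray   # player-frame Voronoi areas, m^2
    free_areas: np.ndarray      # per-frame free-space areas, m^2
    frames: np.ndarray
    horizon_s: float


class _PlayerSeries:
    """Smoothed trajectory, kinematics and frame lookup for one player."""

    def __init__(self, dataset: TrackingDataset, pid, cfg: ModelConfig):
        sub = dataset.player_frame(pid)
        self.frames = sub["frame"].to_numpy()
        self.raw_x = sub["x_m"].to_numpy(float)
        self.raw_y = sub["y_m"].to_numpy(float)
        raw = Trajectory(
            player_id=pid,
            t=sub["time_s"].to_numpy(float),
            x=self.raw_x,
            y=self.raw_y,
        )
        self.traj = smooth_trajectory(raw, cutoff=cfg.cutoff_hz, order=cfg.filter_order)
        self.kin = compute_kinematics(self.traj, stillness_floor=cfg.stillness_floor)

    def index_of(self, frame: int) -> int | None:
        i = int(np.searchsorted(self.frames, frame))
        if i < len(self.frames) and self.frames[i] == frame:
            return i
        return None


def _warn_on_overlap(dataset: TrackingDataset, library: ModelLibrary) -> None:
    index = getattr(library, "training_index", None)
    if not index:
        return
    for pid in dataset.players:
        if pid in index:
            f = dataset.player_frame(pid)["frame"]
            lo, hi = index[pid]
            if f.iloc[-1] >= lo and f.iloc[0] <= hi:
                warnings.warn(
                    "evaluation dataset overlaps the library's training data "
                    f"(player {pid!r}); accuracy will be optimistic"
                )
                return


def _placed_samples(library: ModelLibrary, series: _PlayerSeries, idx: int) -> np.ndarray:
    """Model samples (S, H, 2) placed at the player's state at index idx."""
    model = library.lookup(series.kin.v[idx], series.kin.a[idx])
    placed = _rotate(
        model.samples.astype(float), -rotation_angle(series.kin.theta_d[idx])
    )
    placed[..., 0] += series.traj.x[idx]
    placed[..., 1] += series.traj.y[idx]
    return placed


def _locals_at_frame(
    library: ModelLibrary,
    series_map: dict,
    frame: int,
    lags: list[int],
    mode: str,
):
    """Per-player local probability windows at one frame, per horizon lag."""
    pitch, cfg = library.pitch_config, library.model_config
    out: dict[int, dict] = {L: {} for L in lags}
    for pid, series in series_map.items():
        idx = series.index_of(frame)
        if idx is None or not series.kin.valid[idx]:
            continue
        placed = _placed_samples(library, series, idx)
        for L in lags:
            pts = placed[:, :L, :] if cfg.cumulative else placed[:, L - 1 : L, :]
            out[L][pid] = _local_pipeline(pts.reshape(-1, 2), pitch, cfg, mode)
    return out


def accuracy(
    dataset: TrackingDataset,
    library: ModelLibrary,
    horizons: tuple = (1.0, 2.0, 3.0),
    stride: int = 1,
    mode: str | None = None,
) -> AccuracyReport:
    """Prediction accuracy of dominance maps at the given horizons.

    Every ``stride``-th frame with a full future window is evaluated.  A
    player enters a horizon's denominator at frame t only if their
    kinematic state at t is defined and a real position exists at t + T.
    """
    pitch, cfg = library.pitch_config, library.model_config
    fr = pitch.frame_rate
    lags = [cfg.horizon_frames(fr, T) for T in horizons]
    if max(lags) > library.horizon_frames:
        raise ValueError("requested horizon exceeds the library horizon")
    _warn_on_overlap(dataset, library)
    mode = mode or cfg.normalization

    series_map = {}
    for pid in dataset.players:
        try:
            series_map[pid] = _PlayerSeries(dataset, pid, cfg)
        except ValueError:
            continue  # too short to filter: not evaluable

    hits = {pid: {T: 0 for T in horizons} for pid in series_map}
    counts = {pid: {T: 0 for T in horizons} for pid in series_map}
    frames = dataset.frames[::stride]
    for frame in frames:
        locals_by_lag = _locals_at_frame(library, series_map, frame, lags, mode)
        for T, L in zip(horizons, lags):
            locs = locals_by_lag[L]
            if not locs:
                continue
            order = sorted(locs)
            for pid in order:
                series = series_map[pid]
                fut = series.index_of(frame + L)
                if fut is None:
                    continue
                row, col = pitch.cell_of(series.raw_x[fut], series.raw_y[fut])
                if not pitch.on_pitch_cells(row, col):
                    continue
                rows = np.array([int(row)])
                cols = np.array([int(col)])
                best_val, owner = 0.0, None
                for other in order:  # ascending ids: strict > gives lowest-id ties
                    val = float(locs[other].value_at_cells(rows, cols)[0])
                    if val > best_val:
                        best_val, owner = val, other
                counts[pid][T] += 1
                if owner == pid:
                    hits[pid][T] += 1

    per_player = {
        pid: {
            T: (100.0 * hits[pid][T] / counts[pid][T]) if counts[pid][T] else math.nan
            for T in horizons
        }
        for pid in series_map
    }
    evaluated = {pid: dict(counts[pid]) for pid in series_map}
    return AccuracyReport(horizons=tuple(horizons), per_player=per_player,
                          evaluated=evaluated)


def pass_windows(events: list[PassEvent], frame_rate: float = 30.0) -> WindowReport:
    """Percentiles of successful-pass time windows and the implied horizon."""
    windows = np.array(
        [e.window_s(frame_rate) for e in events if e.success], dtype=float
    )
    if windows.size == 0:
        raise ValueError("no successful pass events")
    p25, p50, p75, p95 = np.percentile(windows, [25, 50, 75, 95])
    return WindowReport(
        n=int(windows.size),
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
        p95=float(p95),
        recommended_horizon_s=math.ceil(float(p95) / 0.5) * 0.5,
    )


def _effect_label(r: float) -> str:
    if r >= 0.5:
        return "large"
    if r >= 0.3:
        return "medium"
    if r >= 0.1:
        return "small"
    return "negligible"


def _bootstrap_median_ci(
    x: np.ndarray, rng: np.random.Generator, n_boot: int = 2000
) -> tuple[float, float]:
    meds = np.median(
        x[rng.integers(0, len(x), size=(n_boot, len(x)))], axis=1
    )
    lo, hi = np.percentile(meds, [2.5, 97.5])
    return float(lo), float(hi)


def compare_areas(
    model_areas: np.ndarray,
    voronoi_areas: np.ndarray,
    seed: int = 0,
    n_boot: int = 2000,
) -> AreaComparison:
    """Rank-sum comparison of player-frame areas with effect size r.

    Uses exact enumeration of the rank-sum null when either sample has at
    most 20 observations, the normal approximation otherwise; r = |Z|/sqrt(N)
    per Rosenthal, labelled per Cohen (small 0.1, medium 0.3, large 0.5).
    """
    x = np.asarray(model_areas, dtype=float)
    y = np.asarray(voronoi_areas, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both area samples must be non-empty")
    N = x.size + y.size
    if min(x.size, y.size) <= 20:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        z = float(stats.norm.isf(min(p, 1.0) / 2.0)) if p < 1.0 else 0.0
    else:
        res = stats.ranksums(x, y)
        z, p = float(res.statistic), float(res.pvalue)
    r = abs(z) / math.sqrt(N)
    rng = np.random.default_rng(seed)
    ci_x = _bootstrap_median_ci(x, rng, n_boot)
    ci_y = _bootstrap_median_ci(y, rng, n_boot)
    xq = np.percentile(x, [25, 50, 75])
    yq = np.percentile(y, [25, 50, 75])
    return AreaComparison(
        model_median=float(xq[1]), model_iqr=float(xq[2] - xq[0]),
        model_p25=float(xq[0]), model_p75=float(xq[2]), model_ci95=ci_x,
        voronoi_median=float(yq[1]), voronoi_iqr=float(yq[2] - yq[0]),
        voronoi_p25=float(yq[0]), voronoi_p75=float(yq[2]), voronoi_ci95=ci_y,
        p_value=p, z=z, r=r, label=_effect_label(r),
        n_model=int(x.size), n_voronoi=int(y.size),
    )


def area_protocol(
    dataset: TrackingDataset,
    library: ModelLibrary,
    horizon_s: float = 3.0,
    stride: int = 1,
    mode: str | None = None,
) -> AreaProtocolResult:
    """Collect model dominant-region, free-space and Voronoi areas per frame.

    Model areas come from the dominance map at ``horizon_s``; Voronoi areas
    from the clipped tessellation of the same frames' positions.  Players
    without a defined kinematic state at a frame contribute no probability
    grid (their cells may fall to others or to free space) but still seed
    the Voronoi tessellation.
    """
    pitch, cfg = library.pitch_config, library.model_config
    fr = pitch.frame_rate
    L = cfg.horizon_frames(fr, horizon_s)
    mode = mode or cfg.normalization
    series_map = {}
    for pid in dataset.players:
        try:
            series_map[pid] = _PlayerSeries(dataset, pid, cfg)
        except ValueError:
            continue

    model_areas, voronoi_areas, free_areas, used_frames = [], [], [], []
    for frame in dataset.frames[::stride]:
        locs = _locals_at_frame(library, series_map, frame, [L], mode)[L]
        if not locs:
            continue
        dmap = _dominance_from_locals(
            locs, pitch, frame=int(frame), horizon_s=horizon_s
        )
        report = region_areas(dmap, pitch)
        model_areas.extend(report.player_areas[p] for p in dmap.players)
        free_areas.append(report.free_area)
        pos = dataset.positions_at(frame)
        positions = {
            row.player_id: (row.x_m, row.y_m) for row in pos.itertuples(index=False)
        }
        vrep = voronoi_regions(positions, pitch, frame=int(frame))
        voronoi_areas.extend(vrep.areas[p] for p in sorted(vrep.areas))
        used_frames.append(int(frame))
    return AreaProtocolResult(
        model_areas=np.asarray(model_areas, dtype=float),
        voronoi_areas=np.asarray(voronoi_areas, dtype=float),
        free_areas=np.asarray(free_areas, dtype=float),
        frames=np.asarray(used_frames, dtype=int),
        horizon_s=horizon_s,
    )


def evaluate_match(
    dataset: TrackingDataset,
    library: ModelLibrary,
    events: list[PassEvent] | None = None,
    horizons: tuple = (1.0, 2.0, 3.0),
    area_horizon_s: float = 3.0,
    stride: int = 1,
    seed: int = 0,
) -> dict:
    """Run all three experiments on one dataset and return a JSON-able report."""
    acc = accuracy(dataset, library, horizons=horizons, stride=stride)
    areas = area_protocol(dataset, library, horizon_s=area_horizon_s, stride=stride)
    comparison = compare_areas(areas.model_areas, areas.voronoi_areas, seed=seed)
    free = areas.free_areas
    pitch_area = library.pitch_config.pitch_area
    report = {
        "accuracy": {
            "per_player": acc.per_player,
            "summary": {
                str(T): s for T, s in acc.summary().items()
            },
        },
        "areas": {
            "model": {
                "median_m2": comparison.model_median,
                "iqr_m2": comparison.model_iqr,
                "ci95_median": comparison.model_ci95,
            },
            "voronoi": {
                "median_m2": comparison.voronoi_median,
                "iqr_m2": comparison.voronoi_iqr,
                "ci95_median": comparison.voronoi_ci95,
            },
            "rank_sum": {
                "p_value": comparison.p_value,
                "z": comparison.z,
                "effect_size_r": comparison.r,
                "label": comparison.label,
            },
            "free_space": {
                "median_m2": float(np.median(free)),
                "iqr_m2": float(np.percentile(free, 75) - np.percentile(free, 25)),
                "min_m2": float(free.min()),
                "max_m2": float(free.max()),
                "median_fraction_of_pitch": float(np.median(free) / pitch_area),
            },
            "horizon_s": area_horizon_s,
            "n_frames": int(len(areas.frames)),
        },
    }
    if events:
        w = pass_windows(events, frame_rate=library.pitch_config.frame_rate)
        report["pass_windows"] = {
            "n": w.n, "p25_s": w.p25, "p50_s": w.p50, "p75_s": w.p75,
            "p95_s": w.p95, "recommended_horizon_s": w.recommended_horizon_s,
        }
    return report
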