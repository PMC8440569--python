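"""Empirical movement models binned by instantaneous speed and acceleration.

For every frame of every trajectory with a defined movement state and a
full future window, the next ``H`` positions are expressed in a canonical
frame: translated so the current position is the origin and rotated so the
instantaneous displacement direction points along +y.  The rotation angle is

    theta_r = 90 + |theta_d|   if theta_d < 0
    theta_r = 90 - theta_d     otherwise

(degrees), i.e. the rotation that carries the displacement direction onto
+y.  Each canonical segment is mirrored about the y axis so left and right
curvature are represented equally, and the (doubled) samples are filed into
the half-open (speed, acceleration) bin containing the frame's v and a —
speeds 0..10 m/s and accelerations -6..6 m/s^2 in unit steps by default.
Each populated bin is a movement model: a cloud of reachable offsets per
future lag 1..H.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import ModelConfig, PitchConfig, config_hash
from .io import TrackingDataset
from .kinematics import KinematicSeries, Trajectory, compute_kinematics, smooth_trajectory

__all__ = [
    "CanonicalSegment",
    "MovementModel",
    "ModelLibrary",
    "rotation_angle",
    "canonicalize",
    "mirror",
    "build_library",
    "save_library",
    "load_library",
]


def rotation_angle(theta_d) -> np.ndarray:
    """Canonicalizing rotation theta_r (degrees) for displacement angle theta_d."""
    theta_d = np.asarray(theta_d, dtype=float)
    return np.where(theta_d < 0, 90.0 + np.abs(theta_d), 90.0 - theta_d)


def _rotate(points: np.ndarray, angle_deg) -> np.ndarray:
    """Rotate (..., 2) points counter-clockwise by angle_deg."""
    rad = np.deg2rad(angle_deg)
    c, s = np.cos(rad), np.sin(rad)
    x, y = points[..., 0], points[..., 1]
    return np.stack([c * x - s * y, s * x + c * y], axis=-1)


@dataclass(frozen=True)
class CanonicalSegment:
    """One frame's future displacements in the canonical (movement-along-+y) frame."""

    theta_r: float
    origin: tuple[float, float]
    fp: np.ndarray          # (H, 2) canonical future positions, lag i = i/frame_rate s
    lag_step_s: float

    @property
    def horizon_frames(self) -> int:
        return self.fp.shape[0]


def canonicalize(
    traj: Trajectory,
    kin: KinematicSeries,
    frame: int,
    horizon_s: float,
) -> CanonicalSegment:
    """Canonical future-position segment anchored at one frame.

    Raises if the frame's kinematics are masked or fewer than
    ``horizon_s * frame_rate`` future samples exist.
    """
    fr = 1.0 / traj.dt
    H = int(round(horizon_s * fr))
    if not kin.valid[frame]:
        raise ValueError(f"frame {frame}: kinematics masked; segment skipped")
    if frame + H > traj.n - 1:
        raise ValueError(f"frame {frame}: fewer than {H} future frames; segment skipped")
    theta_r = float(rotation_angle(kin.theta_d[frame]))
    rel = np.stack(
        [
            traj.x[frame + 1 : frame + H + 1] - traj.x[frame],
            traj.y[frame + 1 : frame + H + 1] - traj.y[frame],
        ],
        axis=-1,
    )
    fp = _rotate(rel, theta_r)
    return CanonicalSegment(
        theta_r=theta_r,
        origin=(float(traj.x[frame]), float(traj.y[frame])),
        fp=fp,
        lag_step_s=traj.dt,
    )


def mirror(samples: np.ndarray) -> np.ndarray:
    """Append the x-negated copy of every sample, doubling the first axis.

    ``samples`` has shape (S, H, 2) (or (H, 2) for a single segment); the
    result stacks originals first, mirrored copies second, so the sample
    set is exactly symmetric under x -> -x at every lag.
    """
    samples = np.asarray(samples)
    if samples.ndim == 2:
        samples = samples[None]
    flipped = samples * np.array([-1.0, 1.0], dtype=samples.dtype)
    return np.concatenate([samples, flipped], axis=0)


@dataclass
class MovementModel:
    """Sample cloud of canonical future offsets for one (v, a) bin.

    ``samples`` has shape (S, H, 2): S mirrored segments by H lags by (x, y)
    metres.  The count per lag is S for every lag, and the set is symmetric
    under x -> -x by construction.
    """

    v_index: int
    a_index: int
    v_range: tuple[float, float]
    a_range: tuple[float, float]
    samples: np.ndarray

    @property
    def sample_count(self) -> int:
        """Samples per lag (mirrored copies included)."""
        return self.samples.shape[0]

    @property
    def horizon_frames(self) -> int:
        return self.samples.shape[1]

    def points_up_to(self, lag: int) -> np.ndarray:
        """Union of canonical samples for lags 1..lag, as an (N, 2) array."""
        if not 1 <= lag <= self.horizon_frames:
            raise ValueError(f"lag must be in 1..{self.horizon_frames}")
        return self.samples[:, :lag, :].reshape(-1, 2)

    def points_at(self, lag: int) -> np.ndarray:
        """Canonical samples at exactly one lag, as an (S, 2) array."""
        if not 1 <= lag <= self.horizon_frames:
            raise ValueError(f"lag must be in 1..{self.horizon_frames}")
        return self.samples[:, lag - 1, :]


@dataclass
class ModelLibrary:
    """All movement models for a dataset, indexed by (v bin, a bin).

    A cell counts as populated when its post-mirroring sample count per lag
    reaches ``model_config.min_samples``; queries on unpopulated or empty
    cells fall back to the nearest populated cell by city-block distance in
    bin units (ties resolved toward lower speed, then lower \\|a\\|).
    """

    pitch_config: PitchConfig
    model_config: ModelConfig
    models: dict = field(default_factory=dict)
    fallback_count: int = 0
    training_index: dict = field(default_factory=dict)  # pid -> (first, last frame)

    @property
    def horizon_frames(self) -> int:
        return self.model_config.horizon_frames(self.pitch_config.frame_rate)

    @property
    def occupancy(self) -> np.ndarray:
        """Boolean (n_speed_bins, n_accel_bins) mask of populated cells."""
        occ = np.zeros(
            (self.model_config.n_speed_bins, self.model_config.n_accel_bins), dtype=bool
        )
        for (vi, ai), m in self.models.items():
            occ[vi, ai] = m.sample_count >= self.model_config.min_samples
        return occ

    @property
    def counts(self) -> np.ndarray:
        c = np.zeros(
            (self.model_config.n_speed_bins, self.model_config.n_accel_bins), dtype=int
        )
        for (vi, ai), m in self.models.items():
            c[vi, ai] = m.sample_count
        return c

    def _nearest_populated(self, vi: int, ai: int) -> tuple[int, int]:
        occ = self.occupancy
        if not occ.any():
            raise ValueError("library has no populated movement model")
        cfg = self.model_config
        a_edges = cfg.accel_edges
        best = None
        for (cvi, cai) in np.argwhere(occ):
            d = abs(int(cvi) - vi) + abs(int(cai) - ai)
            a_center = abs((a_edges[cai] + a_edges[cai + 1]) / 2.0)
            key = (d, int(cvi), a_center, int(cai))
            if best is None or key < best[0]:
                best = (key, (int(cvi), int(cai)))
        return best[1]

    def lookup(self, v: float, a: float) -> MovementModel:
        """Movement model for an instantaneous (v, a), with fallback."""
        vi, ai = self.model_config.bin_of(v, a)
        vi, ai = int(vi), int(ai)
        occ = self.occupancy
        if not occ[vi, ai]:
            vi, ai = self._nearest_populated(vi, ai)
            self.fallback_count += 1
        return self.models[(vi, ai)]


def build_library(
    dataset: TrackingDataset,
    pitch_config: PitchConfig | None = None,
    model_config: ModelConfig | None = None,
) -> ModelLibrary:
    """Build the movement-model library from a tracking dataset.

    Trajectories are smoothed, their kinematics computed, and every valid
    frame with a full future window contributes one mirrored canonical
    segment to the bin holding its (v, a).  Deterministic given dataset and
    configuration; an empty dataset yields an empty (zero-occupancy)
    library.
    """
    pitch_config = pitch_config or dataset.config
    model_config = model_config or ModelConfig()
    lib = ModelLibrary(pitch_config=pitch_config, model_config=model_config)
    H = model_config.horizon_frames(pitch_config.frame_rate)
    per_cell: dict[tuple[int, int], list[np.ndarray]] = {}

    for pid in dataset.players:
        sub = dataset.player_frame(pid)
        lib.training_index[pid] = (int(sub["frame"].iloc[0]), int(sub["frame"].iloc[-1]))
        t = sub["time_s"].to_numpy(float)
        raw = Trajectory(player_id=pid, t=t, x=sub["x_m"].to_numpy(float),
                         y=sub["y_m"].to_numpy(float)) if len(sub) >= 3 else None
        if raw is None:
            continue
        try:
            traj = smooth_trajectory(
                raw, cutoff=model_config.cutoff_hz, order=model_config.filter_order
            )
        except ValueError:
            continue  # too short for the filter: contributes nothing
        kin = compute_kinematics(traj, stillness_floor=model_config.stillness_floor)
        n = traj.n
        if n - 1 - H < 0:
            continue
        anchors = np.flatnonzero(kin.valid[: n - H])
        if anchors.size == 0:
            continue
        # sliding future windows: rel[f, l] = position at anchor+l+1 minus anchor
        win_x = sliding_window_view(traj.x, H + 1)[anchors]
        win_y = sliding_window_view(traj.y, H + 1)[anchors]
        rel_x = win_x[:, 1:] - win_x[:, :1]
        rel_y = win_y[:, 1:] - win_y[:, :1]
        theta_r = rotation_angle(kin.theta_d[anchors])
        rad = np.deg2rad(theta_r)[:, None]
        c, s = np.cos(rad), np.sin(rad)
        fx = c * rel_x - s * rel_y
        fy = s * rel_x + c * rel_y
        fp = np.stack([fx, fy], axis=-1).astype(np.float32)  # (F, H, 2)
        vi, ai = model_config.bin_of(kin.v[anchors], kin.a[anchors])
        order = np.lexsort((ai, vi))
        vi_s, ai_s, fp_s = vi[order], ai[order], fp[order]
        boundaries = np.flatnonzero(np.diff(vi_s) | np.diff(ai_s)) + 1
        for chunk, key_idx in zip(
            np.split(fp_s, boundaries),
            np.concatenate([[0], boundaries]),
        ):
            key = (int(vi_s[key_idx]), int(ai_s[key_idx]))
            per_cell.setdefault(key, []).append(chunk)

    v_edges = model_config.speed_edges
    a_edges = model_config.accel_edges
    cap = model_config.max_segments_per_cell
    for (vi, ai), chunks in sorted(per_cell.items()):
        raw_samples = np.concatenate(chunks, axis=0)
        if cap is not None and raw_samples.shape[0] > cap:
            # deterministic thinning: evenly spaced segments keep the cloud's
            # shape while bounding memory and query cost
            keep = np.floor(
                np.arange(cap) * raw_samples.shape[0] / cap
            ).astype(np.int64)
            raw_samples = raw_samples[keep]
        lib.models[(vi, ai)] = MovementModel(
            v_index=vi,
            a_index=ai,
            v_range=(float(v_edges[vi]), float(v_edges[vi + 1])),
            a_range=(float(a_edges[ai]), float(a_edges[ai + 1])),
            samples=mirror(raw_samples),
        )
    return lib


def save_library(lib: ModelLibrary, path) -> None:
    """Serialize the library to a single .npz archive with a JSON manifest."""
    manifest = {
        "format": "domreg-model-library",
        "version": 1,
        "config_hash": config_hash(lib.pitch_config, lib.model_config),
        "pitch": lib.pitch_config.__dict__,
        "model": lib.model_config.__dict__,
        "cells": [
            {"v_index": vi, "a_index": ai, "sample_count": m.sample_count}
            for (vi, ai), m in sorted(lib.models.items())
        ],
        "training_index": {str(k): v for k, v in lib.training_index.items()},
    }
    arrays = {
        f"cell_{vi}_{ai}": m.samples for (vi, ai), m in lib.models.items()
    }
    np.savez_compressed(path, manifest=json.dumps(manifest, sort_keys=True), **arrays)


def load_library(path) -> ModelLibrary:
    """Load a library saved by :func:`save_library`, validating its manifest."""
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["manifest"]))
        if manifest.get("format") != "domreg-model-library":
            raise ValueError(f"{path}: not a movement-model library archive")
        pitch = PitchConfig(**manifest["pitch"])
        model_cfg = ModelConfig(**manifest["model"])
        if config_hash(pitch, model_cfg) != manifest["config_hash"]:
            raise ValueError(f"{path}: manifest config hash mismatch")
        lib = ModelLibrary(
            pitch_config=pitch,
            model_config=model_cfg,
            training_index={
                k: tuple(v) for k, v in manifest.get("training_index", {}).items()
            },
        )
        v_edges = model_cfg.speed_edges
        a_edges = model_cfg.accel_edges
        for cell in manifest["cells"]:
            vi, ai = cell["v_index"], cell["a_index"]
            samples = data[f"cell_{vi}_{ai}"]
            if samples.shape[0] != cell["sample_count"]:
                raise ValueError(f"{path}: cell ({vi},{ai}) sample count mismatch")
            lib.models[(vi, ai)] = MovementModel(
                v_index=vi,
                a_index=ai,
                v_range=(float(v_edges[vi]), float(v_edges[vi + 1])),
                a_range=(float(a_edges[ai]), float(a_edges[ai + 1])),
                samples=samples,
            )
    return lib
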