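"""Trajectory filtering and instantaneous kinematics.

A player's raw path is low-pass filtered (zero-phase third-order
Butterworth, 0.4 Hz cut-off by default) and three per-frame series are
derived from it:

* ``theta_d`` — displacement angle of the forward step, degrees in
  (-180, 180] measured from the +x (longitudinal) axis;
* ``v``      — speed from central differences of position, m/s;
* ``a``      — signed tangential acceleration, the central difference of
  the speed series, m/s^2.

theta_d uses a forward difference (valid up to frame n-2), v a central
difference (frames 1..n-2) and a a central difference of v (frames
2..n-3), all 0-indexed; the combined validity mask marks frames where
every series is defined.  Frames whose forward step is below the
stillness floor have no defined direction and are masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "Trajectory",
    "KinematicSeries",
    "smooth_trajectory",
    "displacement_angle",
    "velocity",
    "acceleration",
    "compute_kinematics",
]


@dataclass(frozen=True)
class Trajectory:
    """One player's uniformly-sampled 2-D path (seconds, metres)."""

    player_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t, x, y = (np.asarray(v, dtype=float) for v in (self.t, self.x, self.y))
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t, x, y must have equal length")
        if len(t) < 3:
            raise ValueError("trajectory needs at least 3 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        # tolerance admits CSV rounding (1e-6 s) but rejects dropped frames
        if np.ptp(dt) > 1e-5:
            raise ValueError("sampling step must be constant (within 1e-5 s)")

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class KinematicSeries:
    """Per-frame displacement angle (deg), speed (m/s), acceleration (m/s^2).

    Entries are NaN outside their stencil's valid range; ``valid`` is True
    where all three series are defined.
    """

    theta_d: np.ndarray
    v: np.ndarray
    a: np.ndarray
    valid: np.ndarray


def smooth_trajectory(
    traj: Trajectory, cutoff: float = 0.4, order: int = 3
) -> Trajectory:
    """Zero-phase Butterworth low-pass of x and y independently.

    Forward-backward filtering doubles the effective order but introduces
    no phase lag, so filtered positions stay aligned in time with the raw
    series — a prerequisite for building future-position models at fixed
    lags.
    """
    fs = 1.0 / traj.dt
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    b, a = butter(order, cutoff, fs=fs)
    padlen = 3 * max(len(a), len(b))
    if traj.n <= padlen:
        raise ValueError(
            f"trajectory has {traj.n} samples; the order-{order} zero-phase "
            f"filter needs more than {padlen}"
        )
    x = filtfilt(b, a, traj.x)
    y = filtfilt(b, a, traj.y)
    return Trajectory(player_id=traj.player_id, t=traj.t, x=x, y=y)


def displacement_angle(
    traj: Trajectory, stillness_floor: float = 1e-4
) -> np.ndarray:
    """Forward-difference displacement angle, degrees in (-180, 180].

    Frame i holds the angle of (x[i+1]-x[i], y[i+1]-y[i]) from the +x
    axis via the two-argument arctangent; steps shorter than
    ``stillness_floor`` metres and the final frame are NaN.
    """
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    theta = np.degrees(np.arctan2(dy, dx))
    # atan2 returns -180 for (-d, -0.0); fold onto +180 for the (-180, 180] range
    theta[theta == -180.0] = 180.0
    still = np.hypot(dx, dy) < stillness_floor
    theta[still] = np.nan
    out = np.full(traj.n, np.nan)
    out[:-1] = theta
    return out


def velocity(traj: Trajectory) -> np.ndarray:
    """Central-difference speed magnitude, m/s; endpoints NaN."""
    out = np.full(traj.n, np.nan)
    denom = traj.t[2:] - traj.t[:-2]
    vx = (traj.x[2:] - traj.x[:-2]) / denom
    vy = (traj.y[2:] - traj.y[:-2]) / denom
    out[1:-1] = np.hypot(vx, vy)
    return out


def acceleration(traj: Trajectory, v: np.ndarray | None = None) -> np.ndarray:
    """Central difference of the speed series (signed, tangential), m/s^2.

    Two frames at each end are NaN: one lost to the speed stencil, one to
    its own.
    """
    if v is None:
        v = velocity(traj)
    out = np.full(traj.n, np.nan)
    denom = traj.t[2:] - traj.t[:-2]
    out[1:-1] = (v[2:] - v[:-2]) / denom
    return out


def compute_kinematics(
    traj: Trajectory, stillness_floor: float = 1e-4
) -> KinematicSeries:
    """theta_d, v, a aligned to frame i, with the combined validity mask."""
    theta = displacement_angle(traj, stillness_floor=stillness_floor)
    v = velocity(traj)
    a = acceleration(traj, v=v)
    valid = np.isfinite(theta) & np.isfinite(v) & np.isfinite(a)
    return KinematicSeries(theta_d=theta, v=v, a=a, valid=valid)
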