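"""Shared fixtures: small pitch configs and pre-built synthetic libraries.

Everything is generated programmatically and seeded; session-scoped
fixtures cache the expensive builds (movement-model libraries) that
several test modules share.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from domreg import (
    ModelConfig,
    PitchConfig,
    SimConfig,
    TrackingDataset,
    build_library,
    generate_match,
)


@pytest.fixture(scope="session")
def default_pitch() -> PitchConfig:
    return PitchConfig()


@pytest.fixture(scope="session")
def small_pitch() -> PitchConfig:
    """A 20 x 10 m pitch with 0.5 m cells (20 rows x 40 cols) for oracles."""
    return PitchConfig(length_x=20.0, width_y=10.0, cell_size=0.5)


def make_uniform_dataset(
    speeds_and_headings: list[tuple[float, float]],
    starts: list[tuple[float, float]],
    duration_s: float = 20.0,
    frame_rate: float = 30.0,
    config: PitchConfig | None = None,
) -> TrackingDataset:
    """Hand-built constant-velocity dataset (one row per agent per frame)."""
    config = config or PitchConfig()
    n = int(round(duration_s * frame_rate))
    t = np.arange(n) / frame_rate
    frames = np.arange(n)
    records = []
    for k, ((speed, heading_deg), (x0, y0)) in enumerate(
        zip(speeds_and_headings, starts)
    ):
        h = np.deg2rad(heading_deg)
        records.append(
            pd.DataFrame(
                {
                    "frame": frames,
                    "time_s": t,
                    "player_id": f"U{k + 1:02d}",
                    "team": "home" if k % 2 == 0 else "away",
                    "x_m": x0 + speed * np.cos(h) * t,
                    "y_m": y0 + speed * np.sin(h) * t,
                }
            )
        )
    return TrackingDataset(data=pd.concat(records, ignore_index=True), config=config)


@pytest.fixture(scope="session")
def uniform_library():
    """Library trained on hand-built straight-line agents (3 and 5.5 m/s)."""
    ds = make_uniform_dataset(
        [(3.0, 0.0), (5.5, 0.0), (2.0, 90.0), (4.0, 180.0)],
        [(10.0, 10.0), (10.0, 30.0), (50.0, 5.0), (95.0, 55.0)],
        duration_s=15.0,
    )
    cfg = ModelConfig(min_samples=100)
    return build_library(ds, ds.config, cfg), ds


@pytest.fixture(scope="session")
def crw_match():
    """A 6-a-side correlated-random-walk match shared across test modules."""
    sim = SimConfig(n_per_team=6, duration_s=40.0, seed=42)
    return generate_match(sim)


@pytest.fixture(scope="session")
def crw_library(crw_match):
    dataset, _ = crw_match
    return build_library(dataset)
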