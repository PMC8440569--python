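"""Scikit-learn style estimator facade over the dominant-region pipeline.

`DominantRegionModel` is fit/predict shaped: ``fit`` learns the
movement-model library from a tracking dataset, after which dominance
maps, reach-probability grids and prediction accuracy are available.  It
follows the sklearn estimator contract (all constructor args stored
verbatim, fitted state in trailing-underscore attributes, ``get_params``
/ ``set_params`` inherited), so it composes with sklearn's cloning and
model-selection machinery; ``score`` returns the mean fraction of
correct future-position predictions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .config import ModelConfig, PitchConfig
from .dominance import DominanceMap, compute_dominance
from .evaluation import AccuracyReport, accuracy, area_protocol
from .io import TrackingDataset
from .movement import build_library
from .probability import PlayerState, ProbabilityGrid, player_probability

__all__ = ["DominantRegionModel"]


class DominantRegionModel(BaseEstimator):
    """Probabilistic dominant regions learned from tracking data.

    Parameters mirror the pitch raster (105 x 68 m, 0.1 m cells, 30 Hz) and
    the model hyper-parameters: prediction horizon, Gaussian smoothing
    width in grid cells, the 0.001 probability floor, the minimum
    per-bin sample count, and the Butterworth trajectory filter.

    Examples
    --------
    >>> from domreg import DominantRegionModel, SimConfig, generate_match
    >>> train, _ = generate_match(SimConfig(n_per_team=2, duration_s=30, seed=0))
    >>> est = DominantRegionModel().fit(train)
    >>> dmap = est.predict_frame(train, frame=100, horizon_s=1.0)
    """

    def __init__(
        self,
        length_x: float = 105.0,
        width_y: float = 68.0,
        cell_size: float = 0.1,
        frame_rate: float = 30.0,
        horizon_s: float = 3.0,
        sigma_cells: float = 20.0,
        threshold: float = 0.001,
        min_samples: int = 200,
        cutoff_hz: float = 0.4,
        filter_order: int = 3,
        stillness_floor: float = 1e-4,
        cumulative: bool = True,
        normalization: str = "density",
    ):
        self.length_x = length_x
        self.width_y = width_y
        self.cell_size = cell_size
        self.frame_rate = frame_rate
        self.horizon_s = horizon_s
        self.sigma_cells = sigma_cells
        self.threshold = threshold
        self.min_samples = min_samples
        self.cutoff_hz = cutoff_hz
        self.filter_order = filter_order
        self.stillness_floor = stillness_floor
        self.cumulative = cumulative
        self.normalization = normalization

    # -- configuration ----------------------------------------------------
    def pitch_config(self) -> PitchConfig:
        return PitchConfig(
            length_x=self.length_x,
            width_y=self.width_y,
            cell_size=self.cell_size,
            frame_rate=self.frame_rate,
        )

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            horizon_s=self.horizon_s,
            sigma_cells=self.sigma_cells,
            threshold=self.threshold,
            min_samples=self.min_samples,
            cutoff_hz=self.cutoff_hz,
            filter_order=self.filter_order,
            stillness_floor=self.stillness_floor,
            cumulative=self.cumulative,
            normalization=self.normalization,
        )

    @staticmethod
    def _as_dataset(X, config: PitchConfig) -> TrackingDataset:
        if isinstance(X, TrackingDataset):
            return X
        if isinstance(X, pd.DataFrame):
            return TrackingDataset(data=X, config=config)
        raise TypeError(
            "X must be a TrackingDataset or a long-format tracking DataFrame"
        )

    # -- estimator contract ----------------------------------------------
    def fit(self, X, y=None):
        """Build the movement-model library from tracking data X."""
        pitch = self.pitch_config()
        dataset = self._as_dataset(X, pitch)
        self.library_ = build_library(dataset, pitch, self.model_config())
        self.occupancy_ = self.library_.occupancy
        self.n_models_ = int(self.occupancy_.sum())
        self.n_samples_ = int(self.library_.counts.sum())
        return self

    def probability(
        self, state: PlayerState, horizon_s: float | None = None, player_id=None
    ) -> ProbabilityGrid:
        """Reach-probability grid for one instantaneous player state."""
        check_is_fitted(self, "library_")
        return player_probability(
            self.library_, state, horizon_s=horizon_s, player_id=player_id
        )

    def predict_frame(
        self, X, frame: int, horizon_s: float | None = None
    ) -> DominanceMap:
        """Dominance map (owner per cell, 0 = free) for one frame of X."""
        check_is_fitted(self, "library_")
        # honour the fitted library's configuration (it may have been
        # loaded from disk rather than built by fit)
        pitch = self.library_.pitch_config
        cfg = self.library_.model_config
        dataset = self._as_dataset(X, pitch)
        horizon_s = cfg.horizon_s if horizon_s is None else horizon_s
        from .evaluation import _PlayerSeries, _locals_at_frame
        from .dominance import _dominance_from_locals

        series_map = {}
        for pid in dataset.players:
            try:
                series_map[pid] = _PlayerSeries(dataset, pid, cfg)
            except ValueError:
                continue
        L = cfg.horizon_frames(pitch.frame_rate, horizon_s)
        locs = _locals_at_frame(
            self.library_, series_map, frame, [L], cfg.normalization
        )[L]
        if not locs:
            raise ValueError(f"no player has a defined state at frame {frame}")
        return _dominance_from_locals(locs, pitch, frame=frame, horizon_s=horizon_s)

    def evaluate(
        self, X, horizons: tuple = (1.0, 2.0, 3.0), stride: int = 1
    ) -> AccuracyReport:
        """Per-player prediction accuracy of the dominance maps on X."""
        check_is_fitted(self, "library_")
        dataset = self._as_dataset(X, self.pitch_config())
        return accuracy(dataset, self.library_, horizons=horizons, stride=stride)

    def score(self, X, y=None, horizon_s: float = 1.0, stride: int = 15) -> float:
        """Mean fraction of correct predictions at one horizon (0..1)."""
        report = self.evaluate(X, horizons=(horizon_s,), stride=stride)
        vals = report.percents(horizon_s)
        return float(np.mean(vals) / 100.0) if len(vals) else float("nan")
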