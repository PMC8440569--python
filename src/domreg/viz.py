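"""Rendering helpers: probability heat maps, dominance snapshots, accuracy
dot-bar charts and area boxplots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .dominance import DominanceMap
from .probability import ProbabilityGrid

__all__ = [
    "plot_probability",
    "plot_dominance",
    "plot_accuracy",
    "plot_area_boxplots",
]


def _pitch_extent(config):
    return (0.0, config.length_x, 0.0, config.width_y)


def plot_probability(grid: ProbabilityGrid, ax=None, cmap="viridis"):
    """Heat map of one player's reach probabilities."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 6))
    im = ax.imshow(
        grid.values, origin="lower", extent=_pitch_extent(grid.config),
        cmap=cmap, aspect="equal",
    )
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    plt.colorbar(im, ax=ax, label="reach probability")
    return ax


def plot_dominance(dmap: DominanceMap, ax=None, positions: dict | None = None):
    """Dominance snapshot: one colour per player, white for free space."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 6))
    n = len(dmap.players)
    cmap = plt.get_cmap("tab20", max(n, 1))
    colors = np.vstack([[1.0, 1.0, 1.0, 1.0]] + [cmap(i) for i in range(n)])
    from matplotlib.colors import ListedColormap

    ax.imshow(
        dmap.labels, origin="lower", extent=_pitch_extent(dmap.config),
        cmap=ListedColormap(colors), vmin=-0.5, vmax=n + 0.5,
        aspect="equal", interpolation="nearest",
    )
    if positions:
        for pid, (x, y) in positions.items():
            ax.plot(x, y, "ko", ms=3)
            ax.annotate(str(pid), (x, y), fontsize=6)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return ax


def plot_accuracy(report, ax=None):
    """Mean +- sd per horizon with individual player dots."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    summary = report.summary()
    for k, T in enumerate(report.horizons):
        vals = report.percents(T)
        ax.plot(np.full(len(vals), k) + np.linspace(-0.12, 0.12, max(len(vals), 1)),
                vals, ".", color="0.6", ms=4)
        s = summary[T]
        ax.errorbar([k], [s["mean"]], yerr=[s["sd"]], fmt="o", color="C0", capsize=4)
    ax.set_xticks(range(len(report.horizons)))
    ax.set_xticklabels([f"{T:g} s" for T in report.horizons])
    ax.set_ylabel("correct predictions (%)")
    ax.set_xlabel("time-lag window")
    return ax


def plot_area_boxplots(model_areas, voronoi_areas, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(
        [np.asarray(model_areas), np.asarray(voronoi_areas)],
        tick_labels=["movement model", "Voronoi"], showfliers=False,
    )
    ax.set_ylabel("dominant-region area (m$^2$)")
    return ax
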