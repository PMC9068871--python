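"""Static plot exports: score scatter, mixture density, ROC, rank trajectories.

All functions write a PNG and return the path; they are optional sugar over
the TSV outputs and never required by the pipeline itself.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .data import ScoreTable
from .gmm import GmmFit

__all__ = ["plot_score_scatter", "plot_gmm_density", "plot_roc", "plot_rank_lines"]


def plot_score_scatter(
    table: ScoreTable, threshold: float | None, path: str | Path
) -> Path:
    """Accumulated score of every feature, selection threshold as a line."""
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.scatter(range(len(table.feature_ids)), table.accumulated_scores, s=8)
    if threshold is not None:
        ax.axhline(threshold, color="tab:blue", lw=1, label=f"threshold {threshold:.4g}")
        ax.legend()
    ax.set_xlabel("feature index")
    ax.set_ylabel("accumulated score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_gmm_density(
    table: ScoreTable, fit: GmmFit, threshold: float, path: str | Path
) -> Path:
    """Score histogram with the two weighted component densities overlaid."""
    x = table.accumulated_scores
    grid = np.linspace(x.min(), x.max(), 512)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(x, bins=60, density=True, alpha=0.4, color="grey")
    for k, style in ((0, "tab:orange"), (1, "tab:green")):
        dens = (
            fit.weights[k]
            / np.sqrt(2 * np.pi * fit.variances[k])
            * np.exp(-((grid - fit.means[k]) ** 2) / (2 * fit.variances[k]))
        )
        ax.plot(grid, dens, color=style, label=f"component {k}")
    ax.axvline(threshold, color="tab:blue", lw=1, label="threshold")
    ax.set_xlabel("accumulated score")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_roc(points: np.ndarray, auc_value: float, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(points[:, 0], points[:, 1], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("FP rate")
    ax.set_ylabel("TP rate")
    ax.set_title(f"AUC = {auc_value:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_rank_lines(ranks: pd.DataFrame, path: str | Path) -> Path:
    """Per-feature rank across divisions (line chart) plus box summary."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for feature in ranks.columns:
        ax1.plot(ranks.index, ranks[feature], marker="o", ms=3, label=feature)
    ax1.invert_yaxis()
    ax1.set_xlabel("division")
    ax1.set_ylabel("rank")
    if len(ranks.columns) <= 15:
        ax1.legend(fontsize=6)
    ax2.boxplot([ranks[f] for f in ranks.columns], tick_labels=list(ranks.columns))
    ax2.invert_yaxis()
    ax2.set_ylabel("rank")
    ax2.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
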