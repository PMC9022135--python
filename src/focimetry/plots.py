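"""Violin/box and 2D-KDE contour plots for condition comparisons.

Plots are artifacts for human inspection; the numeric report is the
contract.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .quantify import MARKER_FEATURE
from .stats import kde2d

__all__ = ["plot_feature_distributions", "plot_kde_contours"]

_FEATURE_LABEL = {
    "sum_spot_53bp1": "53BP1 sum spot intensity (A.U.)",
    "mean_gh2ax": "gamma-H2AX mean nuclear intensity (A.U.)",
}


def plot_feature_distributions(cells: pd.DataFrame, out_path: str | Path,
                               by: str = "treatment") -> Path:
    """Violin + box plot of both marker features split by condition."""
    conditions = sorted(cells[by].unique())
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, (marker, feature) in zip(axes, MARKER_FEATURE.items()):
        data = [cells.loc[cells[by] == c, feature].to_numpy() for c in conditions]
        ax.violinplot(data, showextrema=False)
        ax.boxplot(data, widths=0.15, showfliers=False)
        ax.set_xticks(range(1, len(conditions) + 1), conditions)
        ax.set_ylabel(_FEATURE_LABEL[feature])
        ax.set_yscale("symlog", linthresh=max(1.0, np.median(np.concatenate(data)) / 10))
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_kde_contours(cells: pd.DataFrame, out_path: str | Path,
                      by: str = "treatment") -> Path:
    """Dual-marker 2D KDE contours, one colour per condition.

    A concerted damage response shows as a diagonal shift of the treated
    density towards higher values of both markers.
    """
    fig, ax = plt.subplots(figsize=(5, 4.5))
    colors = plt.cm.tab10.colors
    for i, (condition, sub) in enumerate(cells.groupby(by)):
        if len(sub) < 3:
            continue
        x = np.log10(sub["sum_spot_53bp1"].to_numpy() + 1.0)
        y = np.log10(sub["mean_gh2ax"].to_numpy() + 1.0)
        grid = kde2d(x, y)
        ax.contour(grid.x, grid.y, grid.density, levels=6,
                   colors=[colors[i % len(colors)]])
        ax.plot([], [], color=colors[i % len(colors)], label=str(condition))
    ax.set_xlabel("log10(1 + 53BP1 sum spot intensity)")
    ax.set_ylabel("log10(1 + gamma-H2AX mean nuclear intensity)")
    ax.legend()
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
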