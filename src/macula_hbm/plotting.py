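"""Minimal figure helpers: grid-map heat maps (with fovea marker) and scree plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .grid_io import GridMap
from .pca import PCDecomposition

__all__ = ["plot_gridmap", "plot_scree"]


def plot_gridmap(gm: GridMap, ax=None, cmap: str = "viridis"):
    """Heat map of a 7x7 grid map; row 1 (superior) on top, col 1 (temporal)
    on the left; white circle marks the fovea."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.0))
    im = ax.imshow(gm.values, cmap=cmap, origin="upper")
    ax.add_patch(
        plt.Circle((gm.fovea[1] - 1, gm.fovea[0] - 1), 0.35, color="white", fill=False, lw=2)
    )
    ax.set_xticks(range(7), [str(c) for c in range(1, 8)])
    ax.set_yticks(range(7), [str(r) for r in range(1, 8)])
    ax.set_xlabel("column (temporal → nasal)")
    ax.set_ylabel("row (superior → inferior)")
    ax.set_title(gm.name, fontsize=9)
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_scree(pc: PCDecomposition, ax=None, label: str = ""):
    """Cumulative variance fraction by component rank."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ranks = np.arange(1, pc.cumulative.size + 1)
    ax.plot(ranks, pc.cumulative, marker="o", ms=3, label=label or pc.kind)
    ax.set_xlabel("principal component rank")
    ax.set_ylabel("cumulative fraction of variance")
    ax.set_ylim(0, 1.02)
    if label or pc.kind:
        ax.legend(fontsize=8)
    return ax
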