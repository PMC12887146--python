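"""Plot helpers for parameter surfaces and bull reaction-norm fans."""

from __future__ import annotations

import numpy as np


def plot_surface(surface, quantity="h2", ax=None):
    """Quantity vs. THI, one line per DIM class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = getattr(surface, quantity if quantity != "h2" else "h2")
    for i, d in enumerate(surface.dim_points):
        ax.plot(surface.thi_points, grid[i], marker="o", label=f"DIMc {i + 1}")
    ax.set_xlabel("THI class")
    ax.set_ylabel({"h2": "heritability"}.get(quantity, quantity))
    ax.legend(fontsize=8)
    return ax


def plot_bull_fans(bvs, bulls, ax=None):
    """305-day breeding value trajectories across THI for selected bulls."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frame = bvs.as_frame()
    for b in bulls:
        ax.plot(bvs.thi_values, frame.loc[b], alpha=0.7, lw=1)
    ax.set_xlabel("THI class")
    ax.set_ylabel("305-day breeding value (kg)")
    return ax


def plot_manhattan(windows, threshold=1.0, ax=None):
    """Window variance shares along the genome with the calling threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    x = 0
    for chrom, grp in windows.groupby("chrom", sort=False):
        xs = np.arange(len(grp)) + x
        ax.scatter(xs, grp["share_pct"], s=4, label=str(chrom))
        x += len(grp)
    ax.axhline(threshold, color="grey", lw=1)
    ax.set_xlabel("window")
    ax.set_ylabel("% slope genetic variance")
    return ax
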