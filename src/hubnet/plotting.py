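"""Figure export: F/F_min traces, connectivity heatmaps, Cartesian
coactivity maps and log-log connectivity distributions.

All functions write straight to file and return nothing; they use the
Agg backend so they are safe in headless runs.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .network import CATEGORY_COLOURS, ConnectivityResult, DegreeDistribution


def plot_traces(traces, path, max_cells: int = 20) -> None:
    """Stacked F/F_min traces for up to ``max_cells`` cells."""
    values = traces.values[:max_cells]
    t = np.arange(values.shape[1]) * traces.frame_interval
    fig, ax = plt.subplots(figsize=(8, 6))
    offset = 0.0
    for row in values:
        ax.plot(t, row + offset, lw=0.6, color="tab:blue")
        offset += max(1.0, row.max() - row.min())
    if traces.stimulus_onset:
        ax.axvline(traces.stimulus_onset * traces.frame_interval,
                   color="red", ls="--", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("F/F_min (stacked)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_heatmap(result: ConnectivityResult, path) -> None:
    """Cell-pair connectivity strength (r) heatmap, 0 to 1."""
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(np.nan_to_num(result.r_matrix), vmin=0, vmax=1,
                   cmap="viridis", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="r")
    ax.set_xlabel("cell")
    ax.set_ylabel("cell")
    ax.set_title(result.islet_id)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_cartesian_map(result: ConnectivityResult, path) -> None:
    """Cartesian coactivity map: edges coloured by r (blue to red, 0-1),
    nodes coloured by coactivity category, positive-label cells ringed
    in black."""
    if result.coords is None:
        raise ValueError("result has no cell coordinates")
    xy = result.coords
    fig, ax = plt.subplots(figsize=(5.5, 5))
    cmap = plt.get_cmap("coolwarm")
    for i, j in zip(*np.nonzero(np.triu(result.sig_mask, k=1))):
        r = result.r_matrix[i, j]
        r = 0.0 if not np.isfinite(r) else max(0.0, min(1.0, r))
        ax.plot(xy[[i, j], 0], xy[[i, j], 1], color=cmap(r), lw=0.6,
                alpha=0.6, zorder=1)
    colours = [CATEGORY_COLOURS[c] for c in result.categories]
    edgecolours = [
        "black" if result.labels is not None and result.labels[i] == "pos" else "0.5"
        for i in range(result.n_cells)
    ]
    linewidths = [
        1.8 if result.labels is not None and result.labels[i] == "pos" else 0.6
        for i in range(result.n_cells)
    ]
    ax.scatter(xy[:, 0], xy[:, 1], c=colours, edgecolors=edgecolours,
               linewidths=linewidths, s=90, zorder=2)
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(result.islet_id)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_degree_distribution(dist: DegreeDistribution, path) -> None:
    """Log-log plot of the binned connectivity distribution with the
    fitted power law."""
    fig, ax = plt.subplots(figsize=(5, 4))
    occ = dist.proportion > 0
    ax.loglog(dist.bin_centres[occ], dist.density[occ], "o", color="tab:green")
    if dist.slope_defined:
        xs = np.geomspace(dist.bin_centres[occ].min(), dist.bin_centres[occ].max(), 50)
        ax.loglog(xs, 10**dist.intercept * xs**dist.slope, "-", color="0.4",
                  label=f"slope {dist.slope:.2f} (R2 {dist.fit_r2:.2f})")
        ax.legend(frameon=False)
    ax.set_xlabel("connectivity (%)")
    ax.set_ylabel("density of cells")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
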