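"""Pearson coactivity networks on binarised Ca2+ activity: pairwise
correlation, circular-shift permutation significance, per-cell
connectivity percentages, node categories, hub classification and the
log-log connectivity distribution.

A *hub* is a cell whose activity is significantly coactive with at
least ``hub_threshold_pct`` (default 30%) of the other cells in the
islet; all remaining cells are *followers*.  Significance of each pair
is assessed against a null built by circularly shifting each cell's
binary vector by a random offset per permutation, which preserves each
cell's burst/run structure while destroying alignment between cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import BinaryRaster, FluorescenceRecording, _check_window
from .traces import normalise_fmin, smooth, binarise

CATEGORY_ORDER = ("ge80", "ge60", "ge40", "lt40")
#: Node colours used in Cartesian coactivity maps.
CATEGORY_COLOURS = {"ge80": "black", "ge60": "grey", "ge40": "white", "lt40": "orange"}


@dataclass
class ConnectivityResult:
    """Full per-islet connectivity analysis output.

    ``r_matrix`` holds pairwise Pearson coefficients on the binarised
    activity (NaN for pairs involving a zero-variance cell);
    ``sig_mask`` the significant connections; ``connectivity_pct[i]``
    is 100 x degree_i / (n_cells - 1).
    """

    r_matrix: np.ndarray
    sig_mask: np.ndarray
    defined: np.ndarray               # per-cell bool: non-zero variance
    connectivity_pct: np.ndarray
    categories: np.ndarray
    hub_flags: np.ndarray
    mean_r: float
    n_permutations: int
    alpha: float
    seed: int
    hub_threshold_pct: float = 30.0
    islet_id: str = ""
    labels: np.ndarray | None = None
    coords: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.r_matrix.shape[0]


@dataclass
class DegreeDistribution:
    """Binned connectivity-percentage distribution with a power-law fit.

    ``proportion`` is the fraction of positive-connectivity cells per
    bin; ``density`` is proportion per unit connectivity (bin-width
    normalised), which is the quantity the slope is fitted on so that
    the exponent of an underlying power law is recovered regardless of
    the (logarithmic) binning.
    """

    bin_edges: np.ndarray
    bin_centres: np.ndarray
    proportion: np.ndarray
    density: np.ndarray
    slope: float
    intercept: float
    fit_r2: float
    slope_defined: bool


# ---------------------------------------------------------------------------
# Pairwise Pearson and permutation significance
# ---------------------------------------------------------------------------


def _standardise(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows standardised to zero mean / unit SD; zero-variance rows
    flagged False and left as zeros."""
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    defined = (sd.ravel() > 0)
    z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return z, defined


def pearson_matrix(raster: BinaryRaster, analysis_window=None) -> np.ndarray:
    """Textbook Pearson coefficient between each pair of cells' binary
    vectors over the window.

    Pairs involving a zero-variance (silent or saturated) cell are NaN;
    the diagonal is 1 for defined cells.
    """
    if raster.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if analysis_window is None:
        analysis_window = (0, raster.n_frames)
    a, b = _check_window(analysis_window, raster.n_frames, "analysis window")
    if b - a < 2:
        raise ValueError("analysis window must contain at least 2 frames")
    x = raster.active[:, a:b].astype(float)
    z, defined = _standardise(x)
    r = (z @ z.T) / x.shape[1]
    np.fill_diagonal(r, 1.0)
    r[~defined, :] = np.nan
    r[:, ~defined] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def permutation_significance(
    raster: BinaryRaster,
    analysis_window=None,
    n_permutations: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Symmetric binary mask of significant connections.

    Null per pair: Pearson r after circularly shifting every cell's
    binary vector by an independent random offset in each permutation.
    A connection is significant iff the observed r exceeds the
    empirical (1 - alpha) tail of its pair's null, i.e. strictly fewer
    than ``alpha * n_permutations`` null values reach the observed r.
    Pairs involving a zero-variance cell are never significant.
    Deterministic under ``seed``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if analysis_window is None:
        analysis_window = (0, raster.n_frames)
    a, b = _check_window(analysis_window, raster.n_frames, "analysis window")
    t = b - a
    if t < 3:
        raise ValueError("analysis window must contain at least 3 frames")

    x = raster.active[:, a:b].astype(float)
    n = x.shape[0]
    z, defined = _standardise(x)
    r_obs = (z @ z.T) / t

    rng = np.random.default_rng(seed)
    cols = np.arange(t)
    exceed = np.zeros((n, n), dtype=np.int64)
    for _ in range(n_permutations):
        offsets = rng.integers(0, t, size=n)
        idx = (cols[None, :] - offsets[:, None]) % t
        zs = np.take_along_axis(z, idx, axis=1)
        r_null = (zs @ zs.T) / t
        exceed += r_null >= r_obs
    sig = exceed < alpha * n_permutations
    sig &= defined[:, None] & defined[None, :]
    np.fill_diagonal(sig, False)
    sig = sig & sig.T  # symmetry guard (counts are symmetric already)
    return sig.astype(np.uint8)


# ---------------------------------------------------------------------------
# Connectivity metrics
# ---------------------------------------------------------------------------


def cell_connectivity(sig_mask: np.ndarray) -> np.ndarray:
    """Per-cell percentage of the remaining n-1 cells with a
    significant connection."""
    m = np.asarray(sig_mask)
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    if not np.array_equal(m, m.T) or np.diagonal(m).any():
        raise ValueError("sig_mask must be symmetric with zero diagonal")
    return 100.0 * m.sum(axis=1) / (n - 1)


def categorise_cells(connectivity_pct) -> np.ndarray:
    """Coactivity categories with lower edges inclusive:
    [80,100] -> ge80, [60,80) -> ge60, [40,60) -> ge40, [0,40) -> lt40.
    """
    pct = np.asarray(connectivity_pct, dtype=float)
    if ((pct < 0) | (pct > 100)).any():
        bad = pct[(pct < 0) | (pct > 100)][0]
        raise ValueError(f"connectivity percentage {bad} outside [0, 100]")
    cats = np.full(pct.shape, "lt40", dtype=object)
    cats[pct >= 40] = "ge40"
    cats[pct >= 60] = "ge60"
    cats[pct >= 80] = "ge80"
    return cats


def classify_hubs(connectivity_pct, hub_threshold_pct: float = 30.0) -> np.ndarray:
    """Hub iff significantly coactive with at least ``hub_threshold_pct``
    percent of the remaining cells (inclusive); others are followers."""
    if not 0 < hub_threshold_pct <= 100:
        raise ValueError("hub_threshold_pct must lie in (0, 100]")
    return np.asarray(connectivity_pct, dtype=float) >= hub_threshold_pct


def fit_loglog(x, y) -> tuple[float, float, float]:
    """Least-squares line on (log10 x, log10 y); returns (slope,
    intercept, r^2).  Requires positive x and y."""
    lx, ly = np.log10(np.asarray(x, float)), np.log10(np.asarray(y, float))
    if lx.size < 2:
        raise ValueError("need at least 2 points for a log-log fit")
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = ((ly - ly.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def _snapped_log_edges(lo: float, hi: float, n_bins: int) -> np.ndarray:
    """Logarithmically spaced edges snapped to half-integers so every
    bin covers a whole number of integer degrees (avoids singleton-bin
    width artefacts for integer-valued connectivity)."""
    raw = np.geomspace(lo, hi, n_bins + 1)
    snapped = np.round(raw - 0.5) + 0.5
    snapped[0] = min(snapped[0], lo - 1e-9)
    snapped[-1] = max(snapped[-1], hi + 1e-9)
    return np.unique(snapped)


def degree_distribution(connectivity_pct, n_bins: int = 20) -> DegreeDistribution:
    """Log-binned distribution of positive connectivity percentages
    with a least-squares power-law fit on the width-normalised
    (density) proportions.

    Raises a distinct error when every cell has zero connectivity; with
    a single occupied bin the slope is undefined and flagged.
    """
    pct = np.asarray(connectivity_pct, dtype=float)
    pos = pct[pct > 0]
    if pos.size == 0:
        raise ValueError("all cells have zero connectivity; no distribution to fit")
    lo, hi = pos.min(), pos.max()
    if lo == hi:
        edges = np.array([lo - 0.5, lo + 0.5])
    else:
        edges = _snapped_log_edges(lo, hi, n_bins)
    counts, edges = np.histogram(pos, bins=edges)
    widths = np.diff(edges)
    centres = np.sqrt(edges[:-1] * np.maximum(edges[1:], 1e-12))
    occupied = counts > 0
    proportion = counts / pos.size
    density = proportion / widths

    if occupied.sum() < 2:
        slope = intercept = r2 = float("nan")
        slope_defined = False
    else:
        slope, intercept, r2 = fit_loglog(centres[occupied], density[occupied])
        slope_defined = True
    return DegreeDistribution(
        bin_edges=edges,
        bin_centres=centres,
        proportion=proportion,
        density=density,
        slope=slope,
        intercept=intercept,
        fit_r2=r2,
        slope_defined=slope_defined,
    )


def summarise_islet(result: ConnectivityResult) -> dict:
    """Scalar summaries: mean off-diagonal r over defined pairs, hub
    fraction (all cells in the denominator), and group mean coactivity
    for hubs and followers."""
    n = result.n_cells
    iu = np.triu_indices(n, k=1)
    r_vals = result.r_matrix[iu]
    mean_r = float(np.nanmean(r_vals)) if np.isfinite(r_vals).any() else float("nan")
    hubs = result.hub_flags.astype(bool)
    pct = result.connectivity_pct
    return {
        "mean_r": mean_r,
        "hub_fraction": float(hubs.sum() / n),
        "mean_hub_coactivity": float(pct[hubs].mean()) if hubs.any() else float("nan"),
        "mean_follower_coactivity": (
            float(pct[~hubs].mean()) if (~hubs).any() else float("nan")
        ),
    }


# ---------------------------------------------------------------------------
# End-to-end per-islet pipeline
# ---------------------------------------------------------------------------


def analyse_recording(
    rec: FluorescenceRecording,
    smooth_seconds: float = 3.0,
    k_mad: float = 3.0,
    n_permutations: int = 1000,
    alpha: float = 0.01,
    hub_threshold_pct: float = 30.0,
    seed: int = 0,
    analysis_window=None,
    baseline_window=None,
    min_scale: float = 0.01,
) -> ConnectivityResult:
    """Full single-islet pipeline: F/F_min -> smooth -> binarise ->
    Pearson + permutation significance -> connectivity metrics.

    Binarisation thresholds come from the pre-stimulus window; the
    connectivity analysis runs on the post-stimulus window (both
    overridable).
    """
    traces = smooth(normalise_fmin(rec), smooth_seconds)
    if baseline_window is None:
        baseline_window = (0, rec.stimulus_onset)
    raster = binarise(traces, k_mad=k_mad, baseline_frames=baseline_window,
                      min_scale=min_scale)
    if analysis_window is None:
        analysis_window = (rec.stimulus_onset, rec.n_frames)
    r = pearson_matrix(raster, analysis_window)
    sig = permutation_significance(
        raster, analysis_window, n_permutations=n_permutations,
        alpha=alpha, seed=seed,
    )
    x = raster.active[:, analysis_window[0]:analysis_window[1]]
    defined = x.std(axis=1) > 0
    pct = cell_connectivity(sig)
    iu = np.triu_indices(rec.n_cells, k=1)
    r_off = r[iu]
    mean_r = float(np.nanmean(r_off)) if np.isfinite(r_off).any() else float("nan")
    return ConnectivityResult(
        r_matrix=r,
        sig_mask=sig,
        defined=defined,
        connectivity_pct=pct,
        categories=categorise_cells(pct),
        hub_flags=classify_hubs(pct, hub_threshold_pct),
        mean_r=mean_r,
        n_permutations=n_permutations,
        alpha=alpha,
        seed=seed,
        hub_threshold_pct=hub_threshold_pct,
        islet_id=rec.islet_id,
        labels=rec.labels,
        coords=rec.coords,
    )


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def per_cell_table(result: ConnectivityResult) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "cell_id": [f"cell{i:03d}" for i in range(result.n_cells)],
            "connectivity_pct": result.connectivity_pct,
            "category": result.categories,
            "hub_flag": result.hub_flags.astype(int),
        }
    )
    df["label"] = result.labels if result.labels is not None else "unknown"
    return df


def write_result(result: ConnectivityResult, out_dir) -> Path:
    """Write r-matrix / sig-mask CSVs, per-cell TSV and GraphML network.

    Returns the output directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = [f"cell{i:03d}" for i in range(result.n_cells)]
    pd.DataFrame(result.r_matrix, index=ids, columns=ids).to_csv(
        out_dir / "r_matrix.csv", float_format="%.6g"
    )
    pd.DataFrame(result.sig_mask, index=ids, columns=ids).to_csv(
        out_dir / "sig_mask.csv"
    )
    per_cell_table(result).to_csv(out_dir / "cells.tsv", sep="\t", index=False)
    import networkx as nx

    nx.write_graphml(to_graph(result), out_dir / "network.graphml")
    return out_dir


def to_graph(result: ConnectivityResult):
    """networkx graph of significant connections with node attributes
    (label, category, hub, x, y) and edge weight r."""
    import networkx as nx

    g = nx.Graph(islet_id=result.islet_id)
    for i in range(result.n_cells):
        attrs = {
            "label": str(result.labels[i]) if result.labels is not None else "unknown",
            "category": str(result.categories[i]),
            "hub": int(result.hub_flags[i]),
            "connectivity_pct": float(result.connectivity_pct[i]),
        }
        if result.coords is not None:
            attrs["x"], attrs["y"] = map(float, result.coords[i])
        g.add_node(f"cell{i:03d}", **attrs)
    for i, j in zip(*np.nonzero(np.triu(result.sig_mask, k=1))):
        r = result.r_matrix[i, j]
        g.add_edge(f"cell{i:03d}", f"cell{j:03d}",
                   r=float(r) if np.isfinite(r) else 0.0)
    return g
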