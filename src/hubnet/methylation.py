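"""Bisulphite clone methylation quantification.

Inputs are clone-by-CpG call matrices (one sequenced clone per row, one
CpG site per column, states methylated / unmethylated / missing) as
produced by amplicon bisulphite cloning-and-sequencing workflows; read
alignment and conversion QC happen upstream.  This module summarises
percent methylation per CpG and per region, compares two sorted
populations with a paired t test across sites, and renders lollipop
(filled/open circle) diagrams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

STATES = ("M", "U", ".")  # methylated, unmethylated, missing


@dataclass
class CloneMethylationMatrix:
    """Clones x CpG sites call matrix for one amplicon in one sample.

    ``cpg_positions`` are 1-based genomic coordinates, strictly
    increasing; ``calls`` entries are 'M', 'U' or '.' (missing).
    """

    region_id: str
    sample_id: str
    cpg_positions: list
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=object)
        if self.calls.ndim != 2 or self.calls.shape[0] < 1:
            raise ValueError("calls must be a 2-D matrix with >= 1 clone")
        pos = np.asarray(self.cpg_positions)
        if pos.size != self.calls.shape[1]:
            raise ValueError("cpg_positions length must match call columns")
        if pos.size and not (np.diff(pos) > 0).all():
            raise ValueError("cpg_positions must be strictly increasing")
        bad = ~np.isin(self.calls, STATES)
        if bad.any():
            clone, site = np.argwhere(bad)[0]
            raise ValueError(
                f"unknown call state {self.calls[clone, site]!r} at clone "
                f"{clone}, site {site} (position {pos[site]})"
            )

    @property
    def n_clones(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]


@dataclass
class MethylationSummary:
    """Per-CpG and pooled-region percent methylation."""

    region_id: str
    sample_id: str
    cpg_positions: list
    per_cpg_pct: np.ndarray        # NaN where a site has no informative call
    per_cpg_informative: np.ndarray
    region_pct: float
    n_clones: int


# ---------------------------------------------------------------------------
# I/O: clone-call TSV dialect — header `clone_id` then one column per CpG
# named by position; values M/U/. ; optional region metadata JSON.
# ---------------------------------------------------------------------------


def read_clone_calls(path, meta_path=None) -> CloneMethylationMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "clone_id":
        raise ValueError(f"{path}: first column must be 'clone_id'")
    site_cols = list(df.columns[1:])
    try:
        positions = [int(c) for c in site_cols]
    except ValueError as exc:
        raise ValueError(f"{path}: CpG columns must be integer positions") from exc
    calls = df[site_cols].fillna(".").to_numpy(dtype=object)

    region_id, sample_id = path.stem, path.stem
    meta_path = Path(meta_path) if meta_path is not None else path.with_suffix(".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        region_id = meta.get("region_id", region_id)
        sample_id = meta.get("sample_id", sample_id)
    return CloneMethylationMatrix(
        region_id=region_id,
        sample_id=sample_id,
        cpg_positions=positions,
        calls=calls,
    )


def write_clone_calls(matrix: CloneMethylationMatrix, path, meta_path=None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        matrix.calls, columns=[str(p) for p in matrix.cpg_positions]
    )
    df.insert(0, "clone_id", [f"clone{i:03d}" for i in range(matrix.n_clones)])
    df.to_csv(path, sep="\t", index=False)
    meta_path = Path(meta_path) if meta_path is not None else path.with_suffix(".json")
    meta_path.write_text(
        json.dumps({"region_id": matrix.region_id, "sample_id": matrix.sample_id})
        + "\n"
    )


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------


def percent_methylation(matrix: CloneMethylationMatrix) -> MethylationSummary:
    """Percent methylation per CpG and pooled across the region.

    Missing calls are excluded.  The region percentage pools all
    informative calls (methylated / informative x 100), which is robust
    to unequal missingness per site; it is *not* the mean of the site
    percentages.  Sites with no informative call get NaN.
    """
    meth = (matrix.calls == "M").sum(axis=0)
    unmeth = (matrix.calls == "U").sum(axis=0)
    informative = meth + unmeth
    if informative.sum() == 0:
        raise ValueError("no informative (M/U) calls in matrix")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_cpg = np.where(
            informative > 0, 100.0 * meth / np.maximum(informative, 1), np.nan
        )
    region_pct = 100.0 * meth.sum() / informative.sum()
    return MethylationSummary(
        region_id=matrix.region_id,
        sample_id=matrix.sample_id,
        cpg_positions=list(matrix.cpg_positions),
        per_cpg_pct=per_cpg,
        per_cpg_informative=informative,
        region_pct=float(region_pct),
        n_clones=matrix.n_clones,
    )


def region_mean_of_sites(summary: MethylationSummary) -> float:
    """Alternative region summary: unweighted mean of defined site
    percentages."""
    return float(np.nanmean(summary.per_cpg_pct))


def compare_populations(a: MethylationSummary, b: MethylationSummary) -> dict:
    """Paired two-sided t test on per-CpG percentages (paired by site).

    Returns the t statistic, p value, number of jointly defined sites,
    the region-level difference (a - b), and a ``zero_variance`` flag
    when all paired differences are identical (t undefined).
    """
    if list(a.cpg_positions) != list(b.cpg_positions):
        raise ValueError("cpg_positions differ between summaries; cannot pair sites")
    x = np.asarray(a.per_cpg_pct, dtype=float)
    y = np.asarray(b.per_cpg_pct, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("need >= 2 sites with defined values in both summaries")
    d = x[ok] - y[ok]
    zero_var = bool(np.allclose(d, d[0]))
    if zero_var:
        # identical differences: t is 0/0 (all zero) or infinite (nonzero)
        if np.allclose(d, 0.0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = float("nan"), float("nan")
    else:
        t_stat, p = sps.ttest_rel(x[ok], y[ok])
        t_stat, p = float(t_stat), float(p)
    return {
        "t": t_stat,
        "p_value": p,
        "n_sites": n,
        "region_difference": a.region_pct - b.region_pct,
        "zero_variance": zero_var,
    }


# ---------------------------------------------------------------------------
# Lollipop rendering
# ---------------------------------------------------------------------------

_GLYPHS = {"M": "●", "U": "○", ".": " "}  # filled / open / gap


def lollipop_text(matrix: CloneMethylationMatrix) -> str:
    """Text lollipop diagram: one row per clone, filled circle =
    methylated, open circle = unmethylated, gap = missing."""
    if matrix.n_sites == 0:
        raise ValueError("empty region: no CpG sites to render")
    header = "positions: " + " ".join(str(p) for p in matrix.cpg_positions)
    rows = [
        f"clone{i:03d} " + " ".join(_GLYPHS[c] for c in matrix.calls[i])
        for i in range(matrix.n_clones)
    ]
    return "\n".join([header] + rows) + "\n"


def lollipop_figure(matrix: CloneMethylationMatrix, path) -> None:
    """Save a lollipop diagram (SVG/PNG by extension), clones stacked
    top to bottom, sites at their genomic positions."""
    if matrix.n_sites == 0:
        raise ValueError("empty region: no CpG sites to render")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pos = np.asarray(matrix.cpg_positions, dtype=float)
    fig, ax = plt.subplots(
        figsize=(max(4.0, matrix.n_sites * 0.5), max(2.0, matrix.n_clones * 0.25))
    )
    span = (pos.max() - pos.min()) or 1.0
    ax.hlines(np.arange(matrix.n_clones), pos.min() - 0.02 * span,
              pos.max() + 0.02 * span, color="0.8", lw=0.8, zorder=1)
    for i in range(matrix.n_clones):
        row = matrix.calls[i]
        for state, face in (("M", "black"), ("U", "white")):
            cols = np.flatnonzero(row == state)
            if cols.size:
                ax.scatter(pos[cols], np.full(cols.size, i), s=60,
                           facecolors=face, edgecolors="black", zorder=2)
    ax.set_yticks(range(matrix.n_clones))
    ax.set_yticklabels([f"clone{i:03d}" for i in range(matrix.n_clones)], fontsize=6)
    ax.invert_yaxis()
    ax.set_xlabel("genomic position (bp)")
    ax.set_title(f"{matrix.region_id} / {matrix.sample_id}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
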