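"""Subpopulation statistics: per-islet hub/follower composition by
label and paired nonparametric comparison across islets.

The paired unit is always the islet: for each islet we compute a
summary per label class (hub:follower ratio or hub percentage, or the
mean glucose-response AUC) and compare the positive and negative
labels across islets with the Wilcoxon matched-pairs signed rank test.
The Wilcoxon implementation is exact (full distribution of the
signed-rank sum, midranks for ties) for up to 25 informative pairs and
uses the tie-corrected normal approximation with continuity correction
beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import stats as sps

from .network import ConnectivityResult
from .traces import FluorescenceRecording, normalise_fmin, smooth, response_auc

EXACT_LIMIT = 25  # largest n_effective for which the exact p is computed


@dataclass
class LabelCounts:
    n_cells: int
    n_hubs: int
    n_followers: int

    @property
    def hub_follower_ratio(self) -> float | None:
        """n_hubs / n_followers; None (undefined) when there are no
        followers."""
        if self.n_followers == 0:
            return None
        return self.n_hubs / self.n_followers

    @property
    def hub_pct(self) -> float | None:
        if self.n_cells == 0:
            return None
        return 100.0 * self.n_hubs / self.n_cells


@dataclass
class IsletHubComparison:
    """Hub and follower counts split by subpopulation label for one
    islet; ``usable`` is False when a label class has no cells."""

    islet_id: str
    pos: LabelCounts
    neg: LabelCounts

    @property
    def usable(self) -> bool:
        return self.pos.n_cells > 0 and self.neg.n_cells > 0


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    n_effective: int
    method: str                   # "exact" | "approximate" | "degenerate"

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0, 1]")


def hub_follower_by_label(
    result: ConnectivityResult, labels=None
) -> IsletHubComparison:
    """Count hubs and followers within the positive and negative label
    classes of one islet ('unknown' cells are excluded)."""
    if labels is None:
        labels = result.labels
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != result.n_cells:
        raise ValueError("labels do not align with cells in the result")
    hubs = np.asarray(result.hub_flags, dtype=bool)
    counts = {}
    for name in ("pos", "neg"):
        mask = labels == name
        n = int(mask.sum())
        nh = int(hubs[mask].sum())
        counts[name] = LabelCounts(n_cells=n, n_hubs=nh, n_followers=n - nh)
    return IsletHubComparison(
        islet_id=result.islet_id, pos=counts["pos"], neg=counts["neg"]
    )


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed rank test
# ---------------------------------------------------------------------------


def _exact_signed_rank_cdf(ranks_x2: np.ndarray, w_x2: int) -> float:
    """P(W+ <= w) under the exact null, by dynamic programming over the
    doubled (integer) midranks.  Handles ties; cost O(n * sum(ranks))."""
    total = int(ranks_x2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks_x2:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    return float(dist[: min(w_x2, total) + 1].sum())


def wilcoxon_matched_pairs(x, y) -> PairedTestResult:
    """Two-sided Wilcoxon matched-pairs signed rank test.

    Differences of zero are dropped (Wilcoxon's convention); |d| are
    ranked with midranks for ties; the statistic is W = min(W+, W-).
    Exact p by full enumeration of the signed-rank distribution for
    n_effective <= 25, otherwise normal approximation with
    tie-corrected variance and continuity correction.  All differences
    zero gives p = 1 with n_effective = 0, flagged as degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with >= 2 pairs")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return PairedTestResult(statistic=0.0, p_value=1.0, n_effective=0,
                                method="degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if n <= EXACT_LIMIT:
        ranks_x2 = np.round(ranks * 2).astype(int)
        p = 2.0 * _exact_signed_rank_cdf(ranks_x2, int(round(w * 2)))
        return PairedTestResult(statistic=w, p_value=min(1.0, p),
                                n_effective=n, method="exact")

    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return PairedTestResult(statistic=w, p_value=1.0, n_effective=n,
                                method="degenerate")
    z = (w - mu + 0.5) / sqrt(var)  # continuity correction toward the mean
    p = 2.0 * sps.norm.cdf(z)
    return PairedTestResult(statistic=w, p_value=float(min(1.0, p)),
                            n_effective=n, method="approximate")


# ---------------------------------------------------------------------------
# Cohort-level comparisons (the paired unit is the islet)
# ---------------------------------------------------------------------------


def _metric_value(counts: LabelCounts, metric: str) -> float | None:
    if metric == "hub_follower_ratio":
        return counts.hub_follower_ratio
    if metric == "hub_pct":
        return counts.hub_pct
    raise ValueError(f"unknown metric '{metric}'")


def cohort_hub_follower_test(
    comparisons: list[IsletHubComparison], metric: str = "hub_follower_ratio"
) -> dict:
    """Paired Wilcoxon across islets on a per-label metric.

    Islets with an empty label class, or an undefined ratio (zero
    followers), are excluded and reported.  Returns the test result
    plus the per-islet value table.
    """
    rows, excluded = [], []
    for comp in comparisons:
        if not comp.usable:
            excluded.append(comp.islet_id)
            continue
        vp = _metric_value(comp.pos, metric)
        vn = _metric_value(comp.neg, metric)
        if vp is None or vn is None:
            excluded.append(comp.islet_id)
            continue
        rows.append((comp.islet_id, vp, vn))
    if len(rows) < 2:
        raise ValueError("need >= 2 islets with both labels for a paired test")
    vp = np.array([r[1] for r in rows])
    vn = np.array([r[2] for r in rows])
    test = wilcoxon_matched_pairs(vp, vn)
    return {
        "metric": metric,
        "test": test,
        "islet_ids": [r[0] for r in rows],
        "positive": vp,
        "negative": vn,
        "excluded": excluded,
        "mean_difference": float(np.mean(vp - vn)),
    }


def compare_auc_by_label(
    recordings: list[FluorescenceRecording],
    window=None,
    smooth_seconds: float = 3.0,
) -> dict:
    """Per islet, mean glucose-response AUC over positive and negative
    cells; Wilcoxon matched-pairs across islets on the per-islet means.

    Islets missing a label class are excluded and reported.
    """
    rows, excluded = [], []
    for rec in recordings:
        traces = smooth(normalise_fmin(rec), smooth_seconds)
        win = window if window is not None else (rec.stimulus_onset, rec.n_frames)
        auc = response_auc(traces, win)
        pos = rec.labels == "pos"
        neg = rec.labels == "neg"
        if not pos.any() or not neg.any():
            excluded.append(rec.islet_id)
            continue
        rows.append((rec.islet_id, float(auc[pos].mean()), float(auc[neg].mean())))
    if len(rows) < 2:
        raise ValueError("need >= 2 islets with both labels for a paired test")
    vp = np.array([r[1] for r in rows])
    vn = np.array([r[2] for r in rows])
    return {
        "test": wilcoxon_matched_pairs(vp, vn),
        "islet_ids": [r[0] for r in rows],
        "auc_pos": vp,
        "auc_neg": vn,
        "excluded": excluded,
        "mean_difference": float(np.mean(vp - vn)),
    }
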