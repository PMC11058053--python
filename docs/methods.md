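# Methods

## Scope and model

`hubnet` analyses functional connectivity among beta cells in Ca²⁺-imaged
islets. The object of interest is the *coactivity network*: cells are nodes,
and an edge connects two cells whose binarised activity is more aligned than
expected for independent cells with the same burst structure. A **hub** is a
cell significantly coactive with at least 30% of the remaining cells of its
islet (threshold configurable, inclusive at the bound); every other cell is a
**follower**. The package quantifies hub/follower composition per labelled
subpopulation within each islet and compares labels across islets with a
paired nonparametric test. A separate module quantifies clone-level
bisulphite CpG methylation of amplicons in sorted populations.

## Trace processing

- **F/F_min.** Each cell's trace is divided by its own minimum over the full
  recording, so the per-cell minimum is exactly 1. The full-recording
  minimum is the default because it requires no window choice; normalising
  by the pre-stimulus mean is available (`method="prestim_mean"`) for
  recordings whose baseline drifts.
- **Smoothing.** Centred moving average, window `round(w_s / dt)` frames
  forced odd (default 3 s). Edges use shrinking windows — the mean of the
  frames actually present — rather than invented padding. Consequence: the
  moving average preserves the mean of a periodic signal over whole periods
  exactly only away from the edges; the property test checks the interior.
- **Binarisation.** Per cell, `threshold = median(baseline) + k·σ̂` with
  `σ̂ = 1.4826·MAD(baseline)` and default `k = 3`; a frame is active iff the
  smoothed value strictly exceeds the threshold. The median/MAD pair makes
  the raster invariant under any positive affine rescaling of a cell's
  trace, so arbitrary fluorescence units cancel. Cells with zero baseline
  MAD fall back to the islet-median σ̂; if that is also zero (synthetic
  noise-free traces) an absolute floor `min_scale` (default 0.01 F/F_min
  units) keeps constant traces inactive.
- **Windows** are half-open `[start, stop)` frame ranges, 0-based; times in
  seconds are `frame × dt`. The response AUC integrates the linear
  interpolant of (F/F_min − 1) from `start·dt` to `stop·dt` (trapezoid), so
  AUCs over adjacent windows sharing an endpoint add exactly; it may be
  negative where smoothing pulls a trace below 1.

## Connectivity and significance

Pairwise Pearson *r* is computed between binary activity vectors over the
post-stimulus window. Zero-variance (silent or saturated) cells give
undefined pairs: excluded from mean *r* and from significance testing, but
retained in cell counts and denominators so per-islet composition matches
the input.

The null model shifts every cell's binary vector circularly by an
independent uniform random offset in each permutation and recomputes all
pairwise *r*. Circular shifts preserve each cell's event-run (burst)
autocorrelation — which frame-wise shuffling would destroy, making the null
far too narrow — while destroying alignment between cells. A connection is
declared significant when strictly fewer than `α·n_permutations` null values
reach the observed *r* (upper tail only: anticorrelation is never a
"connection"). Ties count against significance, which makes the test
conservative; the acceptance suite verifies the empirical false-connection
rate on independent cells stays at or below 1.5·α at α = 0.01. Defaults:
1000 permutations, α = 0.01, seeded and fully deterministic.

Whether published hub analyses threshold significance by surrogate shuffling
or by a fixed r cut-off varies between labs and is often left to supplements;
the circular-shift permutation scheme here is a declared, calibrated choice.

Connectivity percentage uses the remaining `n − 1` cells as denominator
("coactive with X% of the remaining cells"); for islet-sized `n` the
distinction from `n` is negligible but it is applied consistently. Category
bounds (≥80/≥60/≥40/<40) and the hub threshold are inclusive at the lower
edge.

### Degree distribution

Cells with positive connectivity are binned on logarithmic bins whose edges
are snapped to half-integers, so each bin covers a whole number of integer
degrees. Both the raw per-bin proportion and the width-normalised density
are reported; the power-law exponent is fitted by least squares on
(log centre, log density) over occupied bins. Width normalisation matters:
raw proportions on log bins of a d^−γ sequence fit a slope of −γ+1 at the
wide end and −γ−1 at the singleton end, whereas the density recovers −γ
regardless of binning (verified against a d⁻² generator). `fit_r2` is
reported so users can judge linearity; a single occupied bin flags the slope
undefined. The plain least-squares helper `fit_loglog` is exposed for
fitting already-binned proportions.

## Paired subpopulation statistics

The paired unit is the islet, never the cell: per islet and label class the
package computes cell counts, hub counts, hub percentage and the
hub:follower ratio. Ratios with zero followers are undefined and treated as
missing for the paired test (not coerced to 0 or ∞); islets missing a label
class are excluded and reported. Cell-level pooling across islets is
available only as a descriptive summary.

The Wilcoxon matched-pairs signed rank test drops zero differences
(Wilcoxon's convention; the Pratt variant is not implemented), ranks |d|
with midranks for ties, and uses `W = min(W⁺, W⁻)`. For up to 25 informative
pairs the p value is exact: the full null distribution of the signed-rank
sum is built by dynamic programming over the doubled midranks, which remains
exact under ties (scipy's exact mode does not support ties, so it serves
only as a cross-check where both apply). Beyond 25 pairs the tie-corrected
normal approximation with continuity correction is used. Type-I calibration
at n = 20 over 10⁴ null replicates is asserted in the unit suite.

## Methylation quantification

Inputs are clone × CpG matrices with states methylated / unmethylated /
missing at strictly increasing 1-based genomic positions; alignment,
conversion QC and clone deduplication are upstream concerns. Per-CpG percent
methylation excludes missing calls; sites with no informative call are
flagged undefined. The region percentage pools all informative calls
(methylated/informative × 100) rather than averaging site percentages —
robust to unequal missingness per site; the site-mean alternative is exposed
as `region_mean_of_sites`. Populations are compared with a two-sided paired
*t* test across jointly defined CpG sites; identical nonzero differences at
every site make *t* degenerate and are flagged (`zero_variance`) instead of
reported as infinite.

## Synthetic islet generator

The generator emulates a glucose-step imaging session and is the package's
ground-truth source. Defaults (one recording): 50 cells, 2300 frames at
1 s (a ~35 min session with a 200-frame baseline), constant baseline
1.0 a.u. plus optional linear drift, transients with instantaneous unit
rise and 4 s exponential decay, additive Gaussian noise SD 0.2 a.u.
(SNR = 5 against the unit transient), driver event rate 2.5 events/min
post-step, and a positive-label fraction of 0.15 — the order of the
reporter-positive share of the beta-cell compartment in sorted islets.
These rate/noise/duration choices put the binarised rasters in a regime of
short activity runs (~4–6 frames) and moderate occupancy, where the
permutation test has good power per planted link at the defaults; the
regime was chosen by the power analysis below, not fitted to any dataset.

Hub structure is planted in two stages:

1. **Links.** Each of the `round(hub_fraction·n)` hubs (chosen uniformly
   without replacement) is linked to every other cell independently with
   probability `hub_coupling`. Links form the ground-truth adjacency
   (symmetric, hub–hub pairs drawn once).
2. **Recruitment.** Each hub emits events post-step (Bernoulli per frame);
   every event appears in the hub and in a random subset of
   `max(1, round(event_share·n_linked))` of its linked cells at the same
   frame (zero lag, matching the lag-free Pearson statistic). With
   `event_share = 1` every event is broadcast to all linked partners.

The recruitment-subset design is what makes hub/follower analysis
well-posed on synthetic data. If every linked cell received every event (or
an independent thinning of events), any two followers sharing a hub would be
strongly mutually correlated — shared sparse event frames produce Pearson
r ≈ 0.3–0.6 — and essentially all cells would exceed the 30% threshold.
With small recruitment subsets, the hub participates in *every* event while
two of its partners co-occur only at order `event_share²`, so significant
coactivity concentrates on the planted links: hubs sit at ~45% connectivity
and followers at ~14% under defaults, and classification recovers planted
hubs with sensitivity and specificity above 0.9. The trade-off is governed
by a simple budget: per-link correlation is roughly
`r ≈ p_shared / √(p_hub·p_partner)` with `p_shared` capped by
`event_share·rate·run_length`, against a circular-shift null whose 99th
percentile scales as `2.33·√(run_length/T)` — hence the long default
recording and moderate occupancy.

Followers emit *private* (uncorrelated) events at
`event_rate·follower_coupling`; follower "coupling" therefore adds realistic
unshared activity, not planted edges, and the adjacency contains hub links
only. Labels are Bernoulli with probability `label_fraction`, odds-adjusted
for hubs by `label_hub_odds` (values < 1 de-enrich hubs in the positive
label). One `numpy` Generator per islet is consumed in a documented order
(hubs, links, labels, events, recruitments, private events, noise) so
outputs are bit-reproducible across versions; cohort islet *i* uses seed
`base_seed + i`.

What the generator does **not** emulate: biophysical membrane/Ca²⁺ dynamics,
spatial wave propagation with finite velocity, photon/camera noise,
bleaching, motion artefacts, or oscillation-frequency heterogeneity between
cells. Passing tests therefore show that the *pipeline* recovers planted
coactivity structure under realistic noise, not that any particular
biological dataset contains hubs. The clone simulator draws calls
independently per site with per-CpG probabilities and a missingness rate; it
does not model clone relatedness or conversion failure.

## Problem sizes in tests and the acceptance script

Unit and acceptance tests run end-to-end at the default islet size (50
cells × 2300 frames, 1000 permutations). The cohort acceptance check runs
2 × 20 cohorts of 45 islets with 150 permutations per islet — the
permutation count is reduced there purely as a problem-size scaling (α·n
remains ≥ 1); detection operates at hub-vs-threshold margins far wider than
the per-link power lost. The exact planted-graph recovery test uses a
12-cell islet with one hub, zero noise, no private events and one-cell
recruitment, where the significant graph equals the planted star exactly at
α = 0.001. `scripts/acceptance.py` reports recovery over 8 islets and one
effect plus one null cohort; all sizes are stated in its output (`n` per
quantity).

## Known limitations

- Connectivity is undirected and lag-free; leader/wave-latency analysis,
  Granger or transfer-entropy causality are out of scope.
- The permutation null assumes within-cell stationarity of burst structure
  over the analysis window; strong slow trends inside the window would need
  detrending upstream.
- The power-law fit is least squares on binned log densities (as
  conventionally presented for islet connectivity), not a maximum-likelihood
  tail estimator; `fit_r2` is reported so poor linearity is visible.
- Hub:follower ratios are noisy for islets with few labelled cells; the
  hub-percentage metric is provided as a steadier alternative.
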