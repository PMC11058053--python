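# hubnet

Functional-connectivity analysis for pancreatic islet Ca²⁺ imaging —
identification of highly connected **hub** beta cells and paired comparison of
hub/follower composition between labelled beta-cell subpopulations — together
with clone-level bisulphite CpG-methylation quantification for comparing
promoter methylation between sorted populations. A ground-truthed synthetic
islet generator makes every stage of the pipeline testable without imaging
data.

It is written for researchers analysing per-cell fluorescence time series
(cells × frames, with per-cell subpopulation labels such as reporter status)
and clone × CpG bisulphite call matrices.

## The method

For each islet recording:

1. **Normalisation** — each cell's trace is expressed as *F*/*F*<sub>min</sub>
   (fluorescence over its per-cell minimum), then smoothed with a centred
   moving average (default 3 s).
2. **Binarisation** — a frame is *active* when the smoothed trace exceeds
   `median + k·σ̂` of the pre-stimulus baseline, with σ̂ the MAD-based robust
   SD estimate (default k = 3).
3. **Coactivity network** — pairwise Pearson *r* between binary activity
   vectors over the post-stimulus window. Each pair is tested against a null
   built by circularly shifting every cell's vector by a random offset per
   permutation (preserving burst structure, destroying alignment); a
   connection is significant when the observed *r* exceeds the empirical
   (1 − α) tail (defaults: 1000 permutations, α = 0.01).
4. **Hub classification** — a cell's connectivity percentage is
   100·degree/(n − 1) over significant connections. Cells coactive with at
   least 30% of the remaining cells are **hubs**; the rest are **followers**.
   Cells are also binned into the ≥80 / ≥60 / ≥40 / <40% map categories, and
   the log–log connectivity distribution is fitted with a least-squares power
   law.
5. **Subpopulation statistics** — per islet, hub:follower ratios (or hub
   percentages, or glucose-response AUC means) are computed per label class
   and compared across islets with the Wilcoxon matched-pairs signed rank
   test (exact signed-rank distribution with midranks up to 25 informative
   pairs; tie-corrected normal approximation beyond).

The methylation module summarises clone × CpG call matrices (M/U/missing) as
percent methylation per CpG and pooled per region, compares populations with
a paired *t* test across CpG sites, and renders lollipop diagrams.

The synthetic generator plants hub structure explicitly: hubs are linked to a
random subset of the islet (link probability `hub_coupling`, recorded as the
ground-truth adjacency) and every hub event recruits a small random subset of
its linked partners at the same frame, so significant coactivity concentrates
on planted links. Labels, hub-label odds, glucose-step timing, noise and
drift are all configurable; every recording ships with its ground truth.

## Worked example

```bash
python examples/simulate_and_detect_hubs.py
```

```
islet islet000: 50 cells, 2300 frames at 1.0 s
planted hubs:   [1, 21, 24, 36, 46]
recovered hubs: [1, 21, 24, 25, 36, 37, 46]
sensitivity 1.00, specificity 0.96
mean pairwise r 0.052; hub coactivity 44.0% vs follower 14.3%
```

All five planted hubs are recovered (two followers are misclassified, giving
specificity 0.96); hubs are significantly coactive with ~44% of the islet
versus ~14% for followers, so the 30% threshold separates the populations.
The other examples show the cohort-level paired comparison
(`cohort_subpopulation_comparison.py`, Wilcoxon p ≈ 0.002 for a label
carrying hubs at 0.2× odds across 12 islets), the glucose-response AUC
contrast, and clone methylation quantification.

The same stages are available from the shell:

```bash
hubnet simulate --config sim.yaml --out islets/ --n-islets 45 --seed 7
hubnet preprocess --traces islets/islet000.csv --smooth-s 3 --kmad 3 --out islet000.binary.csv
hubnet connect --binary islet000.binary.csv --nperm 1000 --alpha 0.01 --out islet000.net/
hubnet compare --cohort nets/ --metric hub_follower_ratio --out report.json
hubnet methylation --calls pos.tsv neg.tsv --out meth.json --lollipop lollipop.svg
```

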