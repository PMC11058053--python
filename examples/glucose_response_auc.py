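"""Glucose-response AUC compared between labelled subpopulations.

Simulates small islets where positive-label cells respond to the
glucose step with half the Ca2+ transient amplitude, quantifies each
cell's area under the (F/F_min - 1) curve after the step, and compares
per-islet label means with the paired Wilcoxon test.
"""

import dataclasses

import numpy as np

from hubnet import SimulationConfig, simulate_islet, compare_auc_by_label

cfg = SimulationConfig(
    n_cells=20, hub_fraction=0.1, n_frames=400, glucose_step_frame=60,
    noise_sd=0.1, label_fraction=0.3,
)
recordings = []
for i in range(15):
    rec, _ = simulate_islet(dataclasses.replace(cfg, seed=i), f"islet{i:03d}")
    values = rec.values.copy()
    pos = rec.labels == "pos"
    values[pos] = 1.0 + 0.5 * (values[pos] - 1.0)  # blunted responders
    recordings.append(dataclasses.replace(rec, values=np.maximum(values, 1e-3)))

report = compare_auc_by_label(recordings)
test = report["test"]
print("per-islet mean response AUC (dimensionless x s):")
print(f"  positive label: {report['auc_pos'].mean():.1f}")
print(f"  negative label: {report['auc_neg'].mean():.1f}")
print(f"Wilcoxon matched-pairs across {len(report['islet_ids'])} islets: "
      f"p={test.p_value:.4g}")
# the halved transient amplitude shows up as a smaller AUC in the
# positive label; the paired test works on islet means, not cells.
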