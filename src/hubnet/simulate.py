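"""Synthetic islet Ca2+ recordings with planted hub structure, and
synthetic bisulphite clone matrices, each with exported ground truth.

The islet generator emulates a glucose-step experiment: quiet baseline
frames, then oscillatory activity after stimulation.  A minority of
planted *hub* cells drives shared activity: each hub is functionally
linked to a random subset of the islet (link probability
``hub_coupling``; links are the planted adjacency), and every hub
Ca2+ event recruits a small random subset of its linked partners —
``max(1, round(event_share * n_linked))`` cells — at the same frame.
Hubs are therefore active at all of their own events and share a
dedicated slice of them with each partner, while two partners of the
same hub co-occur in a recruitment subset only at second order
(~``event_share``^2), so coactivity concentrates on the planted hub
links — the structure hub/follower analysis is meant to detect.  With
``event_share = 1`` every event is broadcast to all linked partners.
Followers additionally emit private (uncorrelated) events at
``event_rate * follower_coupling``.

Random-stream consumption order (one ``numpy`` Generator per islet,
documented so outputs are reproducible across versions):

1. hub selection, 2. hub->cell links, 3. subpopulation labels,
4. hub event times (hubs in index order), 5. per-event deliveries
(same order), 6. follower private events (followers in index order),
7. additive Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .traces import FluorescenceRecording, write_traces
from .methylation import CloneMethylationMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_islet",
    "simulate_cohort",
    "simulate_clone_matrix",
    "write_islet",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic islet recording.

    Defaults describe a typical glucose-step imaging session: ~18 min
    at 1 Hz with a 100 s pre-stimulus baseline, transients of unit
    amplitude decaying with a 4 s time constant, ~3 driver events per
    minute and noise SD 0.15 a.u. (SNR ~ 6.7).  ``label_fraction``
    defaults to 0.15, the order of the NNAT-positive share of the
    beta-cell compartment; ``label_hub_odds < 1`` de-enriches hubs in
    the positive label.
    """

    n_cells: int = 50
    n_frames: int = 2300
    frame_interval: float = 1.0
    hub_fraction: float = 0.1
    hub_coupling: float = 0.6
    follower_coupling: float = 0.05
    event_share: float = 0.15
    event_rate: float = 2.5           # events / min / driver
    label_fraction: float = 0.15
    label_hub_odds: float = 1.0
    glucose_step_frame: int = 200
    noise_sd: float = 0.2             # fluorescence a.u.
    drift_per_frame: float = 0.0      # a.u. / frame
    amplitude: float = 1.0            # transient peak, a.u.
    decay_s: float = 4.0              # transient decay constant, s
    baseline: float = 1.0             # a.u.
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.n_cells >= 1, "n_cells must be a positive integer"),
            (self.n_frames >= 1, "n_frames must be a positive integer"),
            (self.frame_interval > 0, "frame_interval must be > 0 seconds"),
            (0 <= self.hub_fraction <= 1, "hub_fraction must lie in [0, 1]"),
            (0 <= self.hub_coupling <= 1, "hub_coupling must lie in [0, 1]"),
            (
                0 <= self.follower_coupling <= 1,
                "follower_coupling must lie in [0, 1]",
            ),
            (
                self.follower_coupling < self.hub_coupling
                or self.hub_coupling == 0,
                "follower_coupling must be < hub_coupling",
            ),
            (0 <= self.event_share <= 1, "event_share must lie in [0, 1]"),
            (self.event_rate >= 0, "event_rate must be >= 0 events/min"),
            (0 <= self.label_fraction <= 1, "label_fraction must lie in [0, 1]"),
            (self.label_hub_odds > 0, "label_hub_odds must be positive"),
            (
                0 <= self.glucose_step_frame < self.n_frames,
                "glucose_step_frame must be < n_frames",
            ),
            (self.noise_sd >= 0, "noise_sd must be >= 0"),
            (
                self.hub_fraction == 0 or self.hub_fraction * self.n_cells >= 1,
                "hub_fraction * n_cells must be >= 1 when hub_fraction > 0",
            ),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(message)

    @property
    def n_hubs(self) -> int:
        return int(round(self.hub_fraction * self.n_cells))


@dataclass
class GroundTruth:
    """Planted structure of a simulated islet."""

    hub_ids: set
    labels: np.ndarray            # per-cell 0/1 (1 = positive label)
    event_times: dict             # driver cell -> list of frame indices
    adjacency: np.ndarray         # planted propagation links, symmetric

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.diagonal(a).any():
            raise ValueError("adjacency must be symmetric with zero diagonal")


def _transient_kernel(cfg: SimulationConfig) -> np.ndarray:
    """Instantaneous rise, exponential decay; truncated at 6 decay
    constants."""
    n = max(1, int(np.ceil(6 * cfg.decay_s / cfg.frame_interval)))
    t = np.arange(n) * cfg.frame_interval
    return cfg.amplitude * np.exp(-t / cfg.decay_s)


def simulate_islet(
    config: SimulationConfig, islet_id: str = "islet000"
) -> tuple[FluorescenceRecording, GroundTruth]:
    """Simulate one islet recording; identical configs give identical
    output."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, t_total = cfg.n_cells, cfg.n_frames
    step = cfg.glucose_step_frame
    t_post = t_total - step
    p_event = cfg.event_rate * cfg.frame_interval / 60.0

    # 1. hub selection
    hubs = np.sort(rng.choice(n, size=cfg.n_hubs, replace=False))
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hubs] = True

    # 2. links: planted adjacency (hub-hub pairs drawn once)
    adjacency = np.zeros((n, n), dtype=np.uint8)
    for h in hubs:
        draws = rng.random(n) < cfg.hub_coupling
        for c in np.flatnonzero(draws):
            if c == h:
                continue
            if is_hub[c] and c < h and adjacency[h, c] == 0:
                # pair already decided by the lower-index hub's draw
                continue
            adjacency[h, c] = adjacency[c, h] = 1

    # 3. labels (hubs get odds-adjusted positive probability)
    p = cfg.label_fraction
    if p in (0.0, 1.0):
        p_hub = p
    else:
        odds = p / (1 - p) * cfg.label_hub_odds
        p_hub = odds / (1 + odds)
    p_cell = np.where(is_hub, p_hub, p)
    labels01 = (rng.random(n) < p_cell).astype(np.uint8)

    # 4./5. hub events and deliveries
    impulses = np.zeros((n, t_total))
    event_times: dict[int, list[int]] = {}
    for h in hubs:
        frames = step + np.flatnonzero(rng.random(t_post) < p_event)
        event_times[int(h)] = [int(f) for f in frames]
        impulses[h, frames] += 1.0
        linked = np.flatnonzero(adjacency[h])
        if frames.size and linked.size and cfg.event_share > 0:
            m = min(linked.size, max(1, int(round(cfg.event_share * linked.size))))
            for f in frames:
                recruits = rng.choice(linked, size=m, replace=False)
                impulses[recruits, f] += 1.0

    # 6. follower private events
    p_private = p_event * cfg.follower_coupling
    for c in range(n):
        if is_hub[c]:
            continue
        frames = step + np.flatnonzero(rng.random(t_post) < p_private)
        if frames.size:
            event_times[int(c)] = [int(f) for f in frames]
            impulses[c, frames] += 1.0

    # assemble traces: baseline + drift + transients + noise
    kernel = _transient_kernel(cfg)
    signal = np.empty_like(impulses)
    for c in range(n):
        signal[c] = np.convolve(impulses[c], kernel)[:t_total]
    drift = cfg.drift_per_frame * np.arange(t_total)

    # 7. noise
    noise = (
        rng.normal(0.0, cfg.noise_sd, size=(n, t_total))
        if cfg.noise_sd > 0
        else np.zeros((n, t_total))
    )
    values = np.maximum(cfg.baseline + drift + signal + noise, 1e-3)

    coords = _layout_coords(n)
    labels = np.where(labels01 == 1, "pos", "neg").astype(object)
    rec = FluorescenceRecording(
        islet_id=islet_id,
        values=values,
        frame_interval=cfg.frame_interval,
        labels=labels,
        stimulus_onset=step,
        coords=coords,
    )
    truth = GroundTruth(
        hub_ids=set(int(h) for h in hubs),
        labels=labels01,
        event_times=event_times,
        adjacency=adjacency,
    )
    return rec, truth


def _layout_coords(n: int) -> np.ndarray:
    """Deterministic sunflower layout (micrometre scale) for map export."""
    k = np.arange(n)
    r = 60.0 * np.sqrt((k + 0.5) / n)
    theta = k * np.pi * (3 - np.sqrt(5))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_cohort(
    config: SimulationConfig, n_islets: int, base_seed: int
) -> list[tuple[FluorescenceRecording, GroundTruth]]:
    """Simulate ``n_islets`` independent islets; islet ``i`` uses seed
    ``base_seed + i`` and a distinct islet_id."""
    if n_islets < 1:
        raise ValueError("n_islets must be >= 1")
    out = []
    for i in range(n_islets):
        cfg_i = replace(config, seed=base_seed + i)
        out.append(simulate_islet(cfg_i, islet_id=f"islet{i:03d}"))
    return out


def simulate_clone_matrix(
    n_clones: int,
    cpg_positions,
    per_cpg_prob,
    missing_prob: float = 0.0,
    seed: int = 0,
    region_id: str = "region",
    sample_id: str = "sample",
) -> CloneMethylationMatrix:
    """Clones x CpG calls: each call independently methylated with its
    site probability, then set missing with ``missing_prob``."""
    positions = [int(p) for p in cpg_positions]
    probs = np.asarray(per_cpg_prob, dtype=float)
    if len(positions) != probs.size:
        raise ValueError(
            f"cpg_positions (len {len(positions)}) and per_cpg_prob "
            f"(len {probs.size}) must have equal length"
        )
    if n_clones < 1:
        raise ValueError("n_clones must be a positive integer")
    if ((probs < 0) | (probs > 1)).any() or not 0 <= missing_prob <= 1:
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    meth = rng.random((n_clones, probs.size)) < probs
    calls = np.where(meth, "M", "U").astype(object)
    missing = rng.random((n_clones, probs.size)) < missing_prob
    calls[missing] = "."
    return CloneMethylationMatrix(
        region_id=region_id,
        sample_id=sample_id,
        cpg_positions=positions,
        calls=calls,
    )


def write_islet(
    rec: FluorescenceRecording, truth: GroundTruth, out_dir, stem: str | None = None
) -> Path:
    """Write a recording as trace CSV + metadata sidecar + ground-truth
    JSON; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or rec.islet_id
    csv_path = out_dir / f"{stem}.csv"
    write_traces(rec, csv_path)
    edges = [
        [int(i), int(j)]
        for i, j in zip(*np.nonzero(np.triu(truth.adjacency)))
    ]
    gt = {
        "hub_ids": sorted(truth.hub_ids),
        "labels": [int(x) for x in truth.labels],
        "adjacency_edges": edges,
        "event_times": {str(k): v for k, v in sorted(truth.event_times.items())},
    }
    (out_dir / f"{stem}.truth.json").write_text(json.dumps(gt) + "\n")
    return csv_path
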