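"""Fluorescence trace handling: I/O, F/F_min normalisation, smoothing,
binarisation and glucose-response AUC.

The processing chain mirrors common practice in islet Ca2+ imaging:
raw per-cell fluorescence is expressed relative to its minimum
(F/F_min), lightly smoothed with a centred moving average, and
converted to a per-frame active/inactive raster by thresholding above
the pre-stimulus baseline noise (robust median/MAD z-score).  All
window arguments are half-open ``[start, stop)`` frame ranges, 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_LABELS = ("pos", "neg", "unknown")

#: 1.4826 * MAD is a consistent estimator of the standard deviation
#: for Gaussian noise.
MAD_TO_SD = 1.4826


def _check_window(window, n_frames: int, name: str = "window") -> tuple[int, int]:
    start, stop = int(window[0]), int(window[1])
    if not (0 <= start < stop <= n_frames):
        raise ValueError(
            f"{name} [{start}, {stop}) is empty or outside the recording "
            f"(n_frames={n_frames})"
        )
    return start, stop


@dataclass
class FluorescenceRecording:
    """One islet's cells x frames fluorescence matrix with metadata.

    ``values`` are raw fluorescence in arbitrary units and must be
    finite and strictly positive.  ``labels`` holds the per-cell
    subpopulation assignment (``pos`` / ``neg`` / ``unknown``), e.g.
    NNAT reporter status.  ``coords`` are optional (x, y) centroids in
    micrometres used only for map export.
    """

    islet_id: str
    values: np.ndarray
    frame_interval: float
    labels: np.ndarray
    stimulus_onset: int
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x frames matrix")
        bad = ~np.isfinite(self.values) | (self.values <= 0)
        if bad.any():
            cell, frame = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite or non-positive fluorescence at cell {cell}, "
                f"frame {frame} (value={self.values[cell, frame]!r})"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 seconds")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (self.n_cells,):
            raise ValueError(
                f"labels length {self.labels.size} does not match "
                f"cell count {self.n_cells}"
            )
        unknown = set(self.labels) - set(VALID_LABELS)
        if unknown:
            raise ValueError(f"invalid labels {sorted(unknown)}; expected {VALID_LABELS}")
        if not 0 <= self.stimulus_onset < self.n_frames:
            raise ValueError(
                f"stimulus_onset {self.stimulus_onset} outside frame range "
                f"[0, {self.n_frames})"
            )
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (self.n_cells, 2):
                raise ValueError("coords must have shape (n_cells, 2)")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalisedTraces:
    """Dimensionless F/F_min traces (per-cell minimum is exactly 1
    before smoothing; smoothing may pull values slightly below 1)."""

    values: np.ndarray
    frame_interval: float
    provenance: dict = field(default_factory=dict)
    stimulus_onset: int | None = None

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryRaster:
    """Per-cell, per-frame active/inactive matrix plus the thresholds
    that produced it."""

    active: np.ndarray
    threshold_params: dict
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active)
        if not np.isin(self.active, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.active = self.active.astype(np.uint8)

    @property
    def n_cells(self) -> int:
        return self.active.shape[0]

    @property
    def n_frames(self) -> int:
        return self.active.shape[1]


# ---------------------------------------------------------------------------
# I/O: trace CSV dialect
#
# header: cell_id,label,x,y,f0,f1,...,fN  (one row per cell; x/y may be
# empty); metadata JSON sidecar {islet_id, frame_interval_s,
# stimulus_onset_frame}.
# ---------------------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def read_traces(path, meta_path=None) -> FluorescenceRecording:
    """Read a trace CSV (plus its metadata JSON sidecar).

    ``meta_path`` defaults to the CSV path with a ``.json`` suffix.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _sidecar(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("islet_id", "frame_interval_s", "stimulus_onset_frame"):
        if key not in meta:
            raise ValueError(f"metadata {meta_path} missing required field '{key}'")

    df = pd.read_csv(path, dtype={"cell_id": str, "label": str})
    required = ("cell_id", "label", "x", "y")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing header fields {missing}")
    frame_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    if not frame_cols:
        raise ValueError(f"{path}: no frame columns (f0, f1, ...) found")
    frame_cols.sort(key=lambda c: int(c[1:]))

    values = df[frame_cols].to_numpy(dtype=float)
    bad = ~np.isfinite(values) | (values <= 0)
    if bad.any():
        row, col = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-positive or non-numeric fluorescence for cell "
            f"'{df['cell_id'].iloc[row]}' at frame column '{frame_cols[col]}'"
        )
    labels = df["label"].fillna("unknown").to_numpy(dtype=object)
    coords = None
    if df[["x", "y"]].notna().all().all():
        coords = df[["x", "y"]].to_numpy(dtype=float)
    return FluorescenceRecording(
        islet_id=str(meta["islet_id"]),
        values=values,
        frame_interval=float(meta["frame_interval_s"]),
        labels=labels,
        stimulus_onset=int(meta["stimulus_onset_frame"]),
        coords=coords,
    )


def write_traces(rec: FluorescenceRecording, path, meta_path=None) -> None:
    """Write a recording in the trace CSV dialect with JSON sidecar."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _sidecar(path)
    cols = {
        "cell_id": [f"cell{i:03d}" for i in range(rec.n_cells)],
        "label": rec.labels,
        "x": rec.coords[:, 0] if rec.coords is not None else [""] * rec.n_cells,
        "y": rec.coords[:, 1] if rec.coords is not None else [""] * rec.n_cells,
    }
    df = pd.DataFrame(cols)
    frames = pd.DataFrame(
        rec.values, columns=[f"f{j}" for j in range(rec.n_frames)]
    )
    pd.concat([df, frames], axis=1).to_csv(path, index=False, float_format="%.12g")
    meta = {
        "islet_id": rec.islet_id,
        "frame_interval_s": rec.frame_interval,
        "stimulus_onset_frame": rec.stimulus_onset,
    }
    meta_path.write_text(json.dumps(meta, indent=1) + "\n")


def write_raster(raster: BinaryRaster, path, meta: dict | None = None,
                 meta_path=None) -> None:
    """Write a binary raster as CSV (cell_id, f0..fN of 0/1) with a JSON
    sidecar holding frame metadata and the thresholds used."""
    path = Path(path)
    df = pd.DataFrame(
        raster.active, columns=[f"f{j}" for j in range(raster.n_frames)]
    )
    df.insert(0, "cell_id", [f"cell{i:03d}" for i in range(raster.n_cells)])
    df.to_csv(path, index=False)
    params = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in raster.threshold_params.items()
    }
    payload = {"frame_interval_s": raster.frame_interval,
               "threshold_params": params, **(meta or {})}
    meta_path = Path(meta_path) if meta_path is not None else _sidecar(path)
    meta_path.write_text(json.dumps(payload) + "\n")


def read_raster(path, meta_path=None) -> tuple[BinaryRaster, dict]:
    """Read a binary raster CSV plus its sidecar; returns (raster, meta)."""
    path = Path(path)
    df = pd.read_csv(path)
    frame_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    frame_cols.sort(key=lambda c: int(c[1:]))
    meta_path = Path(meta_path) if meta_path is not None else _sidecar(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    raster = BinaryRaster(
        active=df[frame_cols].to_numpy(dtype=int),
        threshold_params=meta.get("threshold_params", {}),
        frame_interval=meta.get("frame_interval_s"),
    )
    return raster, meta


# ---------------------------------------------------------------------------
# Processing
# ---------------------------------------------------------------------------


def normalise_fmin(rec, method: str = "global_min") -> NormalisedTraces:
    """Express each cell's trace relative to its own baseline (F/F_min).

    ``method='global_min'`` divides by the per-cell minimum over the
    whole recording, so every output row has minimum exactly 1.
    ``method='prestim_mean'`` divides by the pre-stimulus mean instead
    (requires a recording with ``stimulus_onset > 0``).
    """
    values = np.asarray(rec.values, dtype=float)
    stim = getattr(rec, "stimulus_onset", None)
    if method == "global_min":
        denom = values.min(axis=1, keepdims=True)
    elif method == "prestim_mean":
        if not stim:
            raise ValueError("prestim_mean normalisation needs stimulus_onset > 0")
        denom = values[:, :stim].mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown normalisation method '{method}'")
    if (denom <= 0).any():
        cell = int(np.argwhere(denom.ravel() <= 0)[0][0])
        raise ValueError(f"cell {cell} has non-positive baseline; cannot normalise")
    prov = dict(getattr(rec, "provenance", {}))
    prov["normalisation"] = method
    return NormalisedTraces(
        values=values / denom,
        frame_interval=rec.frame_interval,
        provenance=prov,
        stimulus_onset=stim,
    )


def smooth(traces: NormalisedTraces, window_seconds: float) -> NormalisedTraces:
    """Centred moving average with an odd window of
    ``round(window_seconds / frame_interval)`` frames.

    Edges use shrinking windows (the average of the frames actually
    available) rather than invented padding values.
    """
    if window_seconds <= 0:
        raise ValueError("window_seconds must be positive")
    if window_seconds < traces.frame_interval:
        raise ValueError(
            f"window_seconds={window_seconds} is shorter than one frame "
            f"({traces.frame_interval} s)"
        )
    w = int(round(window_seconds / traces.frame_interval))
    if w % 2 == 0:
        w += 1
    if w <= 1:
        out = traces.values.copy()
    else:
        kernel = np.ones(w)
        counts = np.convolve(np.ones(traces.n_frames), kernel, mode="same")
        out = np.empty_like(traces.values)
        for i in range(traces.n_cells):
            out[i] = np.convolve(traces.values[i], kernel, mode="same") / counts
    prov = dict(traces.provenance)
    prov["smooth_window_s"] = window_seconds
    prov["smooth_window_frames"] = w
    return NormalisedTraces(
        values=out,
        frame_interval=traces.frame_interval,
        provenance=prov,
        stimulus_onset=traces.stimulus_onset,
    )


def binarise(
    traces: NormalisedTraces,
    k_mad: float = 3.0,
    baseline_frames=None,
    min_scale: float = 0.01,
) -> BinaryRaster:
    """Threshold each cell above its baseline noise.

    Per cell, ``threshold = median(baseline) + k_mad * sigma`` where
    ``sigma = 1.4826 * MAD(baseline)`` estimates the baseline SD.  A
    frame is active iff the (smoothed) value strictly exceeds the
    threshold.  Cells whose baseline MAD is zero fall back to the
    islet-median sigma; if that is also zero (noise-free traces) an
    absolute floor ``min_scale`` (F/F_min units) is used so constant
    traces stay inactive.
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be positive")
    if baseline_frames is None:
        if not traces.stimulus_onset:
            raise ValueError("no baseline_frames given and no pre-stimulus window")
        baseline_frames = (0, traces.stimulus_onset)
    start, stop = _check_window(baseline_frames, traces.n_frames, "baseline window")

    baseline = traces.values[:, start:stop]
    med = np.median(baseline, axis=1)
    mad = np.median(np.abs(baseline - med[:, None]), axis=1)
    sigma = MAD_TO_SD * mad
    islet_sigma = float(np.median(sigma))
    fallback = islet_sigma if islet_sigma > 0 else float(min_scale)
    sigma = np.where(sigma > 0, sigma, fallback)

    thresholds = med + k_mad * sigma
    active = (traces.values > thresholds[:, None]).astype(np.uint8)
    return BinaryRaster(
        active=active,
        threshold_params={
            "k_mad": k_mad,
            "baseline_frames": (start, stop),
            "min_scale": min_scale,
            "thresholds": thresholds,
        },
        frame_interval=traces.frame_interval,
    )


def response_auc(traces: NormalisedTraces, window) -> np.ndarray:
    """Trapezoidal area of (F/F_min - 1) over a half-open frame window,
    in dimensionless . seconds.

    The integral runs from ``start * dt`` to ``stop * dt`` using the
    linear interpolant, so AUCs over adjacent windows sharing an
    endpoint add exactly.  May be negative where the smoothed trace
    dips below 1.
    """
    start, stop = _check_window(window, traces.n_frames)
    # include the right-edge sample so [a,b) + [b,c) == [a,c)
    right = min(stop + 1, traces.n_frames)
    seg = traces.values[:, start:right] - 1.0
    return np.trapezoid(seg, dx=traces.frame_interval, axis=1)
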