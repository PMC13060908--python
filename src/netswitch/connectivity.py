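"""Sliding-window dynamic connectivity and static/global-signal summaries.

The window stack is the multilayer network input A_ijs: one symmetric,
non-negatively weighted (negatives clipped to zero), hollow correlation matrix
per sliding window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import NodeTimeSeries

log = logging.getLogger(__name__)


@dataclass
class WindowStack:
    """Node x node x layer connectivity tensor from sliding windows."""

    weights: np.ndarray
    window_length: int
    step: int
    node_labels: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be node x node x layer")
        if len(self.node_labels) != self.weights.shape[0]:
            raise ValueError("one label per node required")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1] (negatives are clipped)")
        if np.any(np.abs(np.diagonal(self.weights)) > 0):
            raise ValueError("diagonals must be zero")
        if not np.allclose(self.weights, self.weights.transpose(1, 0, 2)):
            raise ValueError("each layer must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_layers(self) -> int:
        return self.weights.shape[2]


@dataclass
class ConnectivitySummary:
    """Scan-level static connectivity summaries compared across arousal states."""

    static_corr_mean: float
    gs_corr: np.ndarray  # per-node correlation with the global mean signal

    def __post_init__(self) -> None:
        if not -1 <= self.static_corr_mean <= 1:
            raise ValueError("static_corr_mean must lie in [-1, 1]")
        if np.any(np.abs(self.gs_corr) > 1 + 1e-12):
            raise ValueError("gs_corr values must lie in [-1, 1]")


def window_length_from_seconds(window_seconds: float, tr: float) -> int:
    """Window length in samples for a target duration (default ~3 minutes)."""
    return int(round(window_seconds / tr))


def sliding_window_correlation(
    ts: NodeTimeSeries, window_length: int, step: int = 1
) -> WindowStack:
    """Pearson correlation in each sliding window, negatives clipped to 0.

    Layer s covers samples [s*step, s*step + window_length). A node with zero
    variance inside a window gets zero weights in that window (logged).
    """
    if window_length < 3:
        raise ValueError("window_length must be >= 3 samples")
    if window_length > ts.n_time:
        raise ValueError("window_length exceeds the scan length")
    if step < 1:
        raise ValueError("step must be >= 1")
    n = ts.n_nodes
    n_layers = (ts.n_time - window_length) // step + 1
    weights = np.empty((n, n, n_layers))
    for s in range(n_layers):
        seg = ts.values[:, s * step : s * step + window_length]
        sd = seg.std(axis=1)
        flat = np.where(sd == 0)[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(seg)
        if flat.size:
            log.warning(
                "zero-variance node(s) %s in window %d: correlations set to 0",
                [ts.node_labels[i] for i in flat],
                s,
            )
            c[flat, :] = 0.0
            c[:, flat] = 0.0
        np.clip(c, 0.0, 1.0, out=c)
        np.fill_diagonal(c, 0.0)
        weights[:, :, s] = (c + c.T) / 2  # enforce exact symmetry
    return WindowStack(weights, window_length, step, list(ts.node_labels))


def static_correlation_mean(ts: NodeTimeSeries) -> float:
    """Mean of the upper-triangle full-scan Pearson correlations (unclipped)."""
    sd = ts.values.std(axis=1)
    if np.any(sd == 0):
        bad = [ts.node_labels[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance node(s) {bad}: static correlation undefined")
    c = np.corrcoef(ts.values)
    iu = np.triu_indices(ts.n_nodes, k=1)
    return float(c[iu].mean())


def global_signal_correlation(ts: NodeTimeSeries) -> np.ndarray:
    """Pearson correlation of each node with the across-node mean signal."""
    gs = ts.values.mean(axis=0)
    if gs.std() == 0:
        raise ValueError("global mean signal has zero variance")
    sd = ts.values.std(axis=1)
    if np.any(sd == 0):
        bad = [ts.node_labels[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance node(s) {bad}: correlation undefined")
    x = ts.values - ts.values.mean(axis=1, keepdims=True)
    g = gs - gs.mean()
    return (x @ g) / (np.linalg.norm(x, axis=1) * np.linalg.norm(g))


def connectivity_summary(ts: NodeTimeSeries) -> ConnectivitySummary:
    return ConnectivitySummary(
        static_correlation_mean(ts), global_signal_correlation(ts)
    )
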