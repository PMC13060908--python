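"""Plain-text artifact I/O.

Scans are TSV (rows = nodes, header = node labels transposed as columns per
time point is avoided: rows are nodes, first column the node label) with a
JSON sidecar holding tr/state/seed. Eye traces are single-column CSV with a
JSON sidecar holding the sampling rate and onset index. Everything is
diffable text; no binary formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .community import CommunityAssignment
from .connectivity import WindowStack
from .simulate import EyeTrace, NodeTimeSeries


def write_scan(path: str | Path, ts: NodeTimeSeries, **meta) -> None:
    path = Path(path)
    df = pd.DataFrame(ts.values, index=ts.node_labels)
    df.index.name = "node"
    df.to_csv(path, sep="\t", float_format="%.10g")
    sidecar = {"tr": ts.tr, **meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_scan(path: str | Path) -> tuple[NodeTimeSeries, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scan file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col="node")
    meta = json.loads(path.with_suffix(".json").read_text())
    ts = NodeTimeSeries(df.to_numpy(float), [str(i) for i in df.index], meta["tr"])
    return ts, meta


def write_eye_trace(path: str | Path, trace: EyeTrace) -> None:
    path = Path(path)
    pd.DataFrame({"pupil": trace.samples}).to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "sampling_rate": trace.sampling_rate,
                "scan_onset_index": int(trace.scan_onset_index),
            }
        )
    )


def read_eye_trace(path: str | Path) -> EyeTrace:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"eye trace not found: {path}")
    samples = pd.read_csv(path)["pupil"].to_numpy(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return EyeTrace(samples, meta["sampling_rate"], meta["scan_onset_index"])


def write_stack(path: str | Path, stack: WindowStack) -> None:
    """Long-format CSV (i, j, layer, weight), upper triangle only."""
    n, _, L = stack.weights.shape
    iu, ju = np.triu_indices(n, k=1)
    rows = []
    for s in range(L):
        w = stack.weights[iu, ju, s]
        rows.append(
            pd.DataFrame(
                {"node_i": iu, "node_j": ju, "layer": s, "weight": w}
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.8g")
    Path(path).with_suffix(".json").write_text(
        json.dumps(
            {
                "window_length": stack.window_length,
                "step": stack.step,
                "node_labels": stack.node_labels,
                "n_layers": int(L),
            }
        )
    )


def read_stack(path: str | Path) -> WindowStack:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    labels = meta["node_labels"]
    n, L = len(labels), meta["n_layers"]
    weights = np.zeros((n, n, L))
    i = df["node_i"].to_numpy(int)
    j = df["node_j"].to_numpy(int)
    s = df["layer"].to_numpy(int)
    w = df["weight"].to_numpy(float)
    weights[i, j, s] = w
    weights[j, i, s] = w
    return WindowStack(weights, meta["window_length"], meta["step"], labels)


def write_assignment(path: str | Path, assignment: CommunityAssignment,
                     node_labels: list[str]) -> None:
    n, L = assignment.labels.shape
    rows = {
        "node": np.repeat(node_labels, L),
        "layer": np.tile(np.arange(L), n),
        "label": assignment.labels.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assignment(path: str | Path) -> tuple[CommunityAssignment, list[str]]:
    df = pd.read_csv(path)
    nodes = list(dict.fromkeys(df["node"].astype(str)))
    L = df["layer"].max() + 1
    labels = df["label"].to_numpy(int).reshape(len(nodes), L)
    return CommunityAssignment(labels), nodes
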