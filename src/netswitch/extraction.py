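"""Node time-series extraction from location-by-time data.

Two routes: dual regression against a set of spatial templates (network-level
analysis) and plain parcel averaging (parcel-level analysis). Locations are
abstract rows — no volumetric geometry is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import NodeTimeSeries


@dataclass
class SpatialTemplateSet:
    """Location-by-component spatial maps with component labels."""

    maps: np.ndarray
    component_labels: list[str]

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[1] < 1:
            raise ValueError("maps must be a location x component matrix")
        if len(self.component_labels) != self.maps.shape[1]:
            raise ValueError("one label per component required")
        if np.any(np.all(self.maps == 0, axis=0)):
            raise ValueError("templates contain an all-zero map")


def _check_full_rank(maps: np.ndarray, labels: list[str]) -> None:
    rank = np.linalg.matrix_rank(maps)
    if rank < maps.shape[1]:
        # name the components involved in the collinearity via QR pivoting
        _, r = np.linalg.qr(maps)
        diag = np.abs(np.diag(r))
        bad = [labels[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(
            f"templates are rank deficient (rank {rank} < {maps.shape[1]}); "
            f"collinear components: {bad or labels}"
        )


def dual_regression(
    templates: SpatialTemplateSet,
    data: np.ndarray,
    *,
    demean_volumes: bool = True,
    normalize_timeseries: bool = False,
    tr: float = 1.0,
) -> tuple[NodeTimeSeries, np.ndarray]:
    """Two-stage dual regression.

    Stage 1 regresses each volume (time point) on the spatial templates,
    giving one time series per component; stage 2 regresses each location's
    time series on those component time series, giving subject-specific
    spatial maps. Both stages include an intercept. Volumes are spatially
    demeaned before stage 1 by default (the intercept makes this a no-op for
    the component estimates, but it keeps the stage-1 design well scaled).
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] != templates.maps.shape[0]:
        raise ValueError("templates and data must agree on the number of locations")
    _check_full_rank(templates.maps, templates.component_labels)

    x = data - data.mean(axis=0, keepdims=True) if demean_volumes else data
    n_loc, _ = x.shape
    design1 = np.column_stack([np.ones(n_loc), templates.maps])
    coef1, *_ = np.linalg.lstsq(design1, x, rcond=None)
    ts = coef1[1:]  # component x time

    if normalize_timeseries:
        sd = ts.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        ts = ts / sd

    design2 = np.column_stack([np.ones(ts.shape[1]), ts.T])
    coef2, *_ = np.linalg.lstsq(design2, data.T, rcond=None)
    subject_maps = coef2[1:].T  # location x component

    return NodeTimeSeries(ts, list(templates.component_labels), tr), subject_maps


def parcel_average(
    data: np.ndarray,
    parcel_labels: list[str],
    *,
    parcels: list[str] | None = None,
    tr: float = 1.0,
) -> NodeTimeSeries:
    """Average location time series within parcels.

    ``parcel_labels`` gives one parcel label per data row; the output row
    order follows first appearance in the mapping unless an explicit
    ``parcels`` list is given, in which case every listed parcel must be
    non-empty.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] != len(parcel_labels):
        raise ValueError("one parcel label per location required")
    order: list[str] = []
    for lab in parcel_labels:
        if lab not in order:
            order.append(lab)
    if parcels is not None:
        missing = [p for p in parcels if p not in order]
        if missing:
            raise ValueError(f"empty parcel(s): {missing}")
        order = list(parcels)
    rows = [
        data[[i for i, lab in enumerate(parcel_labels) if lab == p]].mean(axis=0)
        for p in order
    ]
    return NodeTimeSeries(np.vstack(rows), order, tr)
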