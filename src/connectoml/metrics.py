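"""Weighted nodal topology metrics and their sparsity-sweep integration.

Conventions (fixed for the whole pipeline):

* edge length for shortest paths is the reciprocal weight, ``l = 1/w``
  (stronger connections are shorter);
* **DC** is node strength, the sum of incident edge weights;
* **NE** is mean inverse shortest-path length to all other nodes, with
  disconnected pairs contributing zero;
* **BC** is Brandes betweenness with exact shortest-path multiplicity,
  normalized by ``(n-1)(n-2)/2`` so values lie in [0, 1] and are comparable
  across sparsity levels.

Metrics computed at each level of a sparsity sweep are collapsed to one
threshold-free value per node by trapezoidal area under the metric-vs-S
curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import igraph as ig
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import ContractError
from .networks import (
    ConnectivityMatrix,
    ThresholdedNetworkSeries,
    threshold_sweep,
)

__all__ = [
    "NodalMetricVector",
    "METRIC_NAMES",
    "degree_centrality",
    "shortest_path_lengths",
    "nodal_efficiency",
    "betweenness_centrality",
    "integrate_auc",
    "nodal_metric_frame",
    "nodal_feature_table",
]

METRIC_NAMES = ("DC", "NE", "BC")


@dataclass
class NodalMetricVector:
    """Per-ROI values of one nodal metric at one threshold level."""

    roi_labels: list[str]
    metric_name: str
    values: np.ndarray
    threshold: str = "single"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.roi_labels),):
            raise ContractError("one value per ROI required")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ContractError("metric values must be finite and nonnegative")
        if self.metric_name not in METRIC_NAMES:
            raise ContractError(f"unknown metric {self.metric_name!r}")


def _require_nonnegative(net: ConnectivityMatrix) -> None:
    if np.any(net.weights < 0):
        raise ContractError(
            "graph metrics require nonnegative weights "
            "(use the absolute-correlation edge convention)"
        )


def degree_centrality(net: ConnectivityMatrix) -> NodalMetricVector:
    """Node strength: the sum of incident edge weights."""
    _require_nonnegative(net)
    return NodalMetricVector(
        roi_labels=list(net.roi_labels),
        metric_name="DC",
        values=net.weights.sum(axis=1),
        threshold=net.threshold_info or "single",
    )


def shortest_path_lengths(net: ConnectivityMatrix) -> np.ndarray:
    """All-pairs shortest path lengths with edge length 1/w (inf if unreachable)."""
    _require_nonnegative(net)
    w = net.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = dijkstra(csr_matrix(lengths), directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def nodal_efficiency(net: ConnectivityMatrix) -> NodalMetricVector:
    """NE(i) = mean of 1/d(i,j) over j != i, with 1/inf = 0."""
    d = shortest_path_lengths(net)
    n = net.n_rois
    with np.errstate(divide="ignore"):
        inv = np.where(d > 0, 1.0 / d, 0.0)
    inv[~np.isfinite(d)] = 0.0
    values = inv.sum(axis=1) / (n - 1)
    return NodalMetricVector(
        roi_labels=list(net.roi_labels),
        metric_name="NE",
        values=values,
        threshold=net.threshold_info or "single",
    )


def betweenness_centrality(net: ConnectivityMatrix) -> NodalMetricVector:
    """Brandes betweenness on 1/w edge lengths, normalized by (n-1)(n-2)/2."""
    _require_nonnegative(net)
    n = net.n_rois
    rows, cols = np.triu_indices(n, k=1)
    mask = net.weights[rows, cols] > 0
    edges = np.column_stack([rows[mask], cols[mask]])
    lengths = 1.0 / net.weights[rows[mask], cols[mask]]
    g = ig.Graph(n=n, edges=edges.tolist(), directed=False)
    raw = np.asarray(g.betweenness(weights=list(lengths)), dtype=float)
    norm = (n - 1) * (n - 2) / 2.0
    values = raw / norm if norm > 0 else raw
    return NodalMetricVector(
        roi_labels=list(net.roi_labels),
        metric_name="BC",
        values=values,
        threshold=net.threshold_info or "single",
    )


_METRIC_FUNCS = {
    "DC": degree_centrality,
    "NE": nodal_efficiency,
    "BC": betweenness_centrality,
}


def _metric_arrays(
    net: ConnectivityMatrix, metrics: Sequence[str]
) -> dict[str, np.ndarray]:
    """All requested metrics off one igraph build (hot path of the sweep).

    Numerically identical to the per-metric operations above, which remain
    the documented single-metric interface.
    """
    _require_nonnegative(net)
    out: dict[str, np.ndarray] = {}
    if "DC" in metrics:
        out["DC"] = net.weights.sum(axis=1)
    need_paths = [m for m in ("NE", "BC") if m in metrics]
    if need_paths:
        n = net.n_rois
        rows, cols = np.triu_indices(n, k=1)
        mask = net.weights[rows, cols] > 0
        edges = np.column_stack([rows[mask], cols[mask]]).tolist()
        lengths = list(1.0 / net.weights[rows[mask], cols[mask]])
        g = ig.Graph(n=n, edges=edges, directed=False)
        if "NE" in metrics:
            d = np.asarray(g.distances(weights=lengths or None), dtype=float)
            np.fill_diagonal(d, np.inf)  # self term excluded from the mean
            with np.errstate(divide="ignore"):
                inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
            out["NE"] = inv.sum(axis=1) / (n - 1)
        if "BC" in metrics:
            raw = np.asarray(g.betweenness(weights=lengths or None), dtype=float)
            norm = (n - 1) * (n - 2) / 2.0
            out["BC"] = raw / norm if norm > 0 else raw
    return out


def integrate_auc(
    series: Sequence[NodalMetricVector], thresholds: Sequence[float]
) -> np.ndarray:
    """Trapezoidal integral of a nodal metric against S over the sweep."""
    if len(series) != len(thresholds):
        raise ContractError("one metric vector per threshold required")
    if len(series) < 2:
        raise ContractError("AUC integration needs at least 2 thresholds")
    labels = series[0].roi_labels
    for v in series[1:]:
        if v.roi_labels != labels:
            raise ContractError("metric vectors must share one ROI set")
    values = np.stack([v.values for v in series])  # (n_thresholds, n_rois)
    return np.trapezoid(values, np.asarray(thresholds, dtype=float), axis=0)


def nodal_metric_frame(
    net_or_series: ConnectivityMatrix | ThresholdedNetworkSeries,
    metrics: Iterable[str] = METRIC_NAMES,
) -> pd.DataFrame:
    """Metric values for a single network, or AUC-integrated over a sweep.

    Returns a DataFrame indexed by ROI label with one column per metric.
    """
    metrics = list(metrics)
    for m in metrics:
        if m not in _METRIC_FUNCS:
            raise ContractError(f"unknown metric {m!r}")
    if isinstance(net_or_series, ThresholdedNetworkSeries):
        labels = net_or_series.networks[0].roi_labels
        thresholds = np.asarray(net_or_series.thresholds, dtype=float)
        per_net = [_metric_arrays(net, metrics) for net in net_or_series.networks]
        data = {
            m: np.trapezoid(np.stack([arrays[m] for arrays in per_net]),
                            thresholds, axis=0)
            for m in metrics
        }
        return pd.DataFrame(data, index=pd.Index(labels, name="roi"))
    net = net_or_series
    data = _metric_arrays(net, metrics)
    return pd.DataFrame({m: data[m] for m in metrics},
                        index=pd.Index(net.roi_labels, name="roi"))


def nodal_feature_table(
    networks: dict[str, ConnectivityMatrix],
    s_min: float = 0.10,
    s_max: float = 0.40,
    step: float = 0.01,
    metrics: Iterable[str] = METRIC_NAMES,
) -> pd.DataFrame:
    """Per-subject nodal features for a set of modality networks.

    Dense GMN/FBN matrices are swept over the sparsity grid and each metric
    AUC-integrated; the WMN (already FN-thresholded) is evaluated once.
    Returns a long-format DataFrame (modality, roi, metric, value) with
    ``3 x n_rois`` rows per modality for the default metric set.
    """
    frames = []
    for modality, net in networks.items():
        if net.modality == "WMN":
            frame = nodal_metric_frame(net, metrics)
        else:
            frame = nodal_metric_frame(threshold_sweep(net, s_min, s_max, step), metrics)
        long = frame.reset_index().melt(
            id_vars="roi", var_name="metric", value_name="value"
        )
        long.insert(0, "modality", modality)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)
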