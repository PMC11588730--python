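"""Region-to-region functional connectivity and thresholded graph metrics.

The connectome is the Pearson correlation matrix of the parcellated time
series with negative edges set to zero (only positive functional
connections are retained).  From it, three networks are built per subject:
the within-left and within-right hemisphere blocks (half x half) and an
inter-hemispheric network over all nodes that keeps only cross-hemisphere
edges.  Each network is thresholded over a grid of edge weights; nodal
betweenness centrality, degree, and strength are computed at every
threshold and integrated (trapezoid) over the grid into a per-node AUC,
removing the dependence on any single threshold choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import igraph as ig
import numpy as np

from hemilat.io import ParcelTable, RoiTimeSeries

METRICS = ("betweenness", "degree", "strength")


@dataclass
class Connectome:
    """Nonnegative symmetric correlation matrix with unit diagonal."""

    matrix: np.ndarray
    subject_id: str = ""
    group: str = "CTRL"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectome matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("connectome matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("connectome matrix must be nonnegative (negatives are zeroed)")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("connectome diagonal must be exactly 1")
        self.matrix = m

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class HemiNetworks:
    """The three per-subject networks: within-left, within-right, inter."""

    left: np.ndarray
    right: np.ndarray
    inter: np.ndarray


@dataclass(frozen=True)
class NodeMetricAUC:
    """Per-node metric curves over the threshold grid and their integrals."""

    metric: str
    grid: tuple[float, ...]
    curve: np.ndarray  # (n_nodes, n_thresholds)
    auc: np.ndarray  # (n_nodes,)


def compute_rfc(ts: RoiTimeSeries) -> Connectome:
    """Pearson correlation of ROI columns with negative entries set to zero."""
    data = ts.data
    sd = data.std(axis=0)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        raise ValueError(f"{ts.subject_id}: zero-variance ROI column {flat[0] + 1}")
    corr = np.corrcoef(data, rowvar=False)
    corr = np.clip(corr, 0.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return Connectome(matrix=corr, subject_id=ts.subject_id, group=ts.group)


def partition_hemispheres(
    c: Connectome, parcels: ParcelTable, inter_network: str = "cross_only"
) -> HemiNetworks:
    """Split the connectome into within-left, within-right, and inter networks.

    ``inter_network="cross_only"`` (default) zeroes the within-hemisphere
    blocks (including the diagonal) so only cross-hemisphere edges remain;
    ``"full"`` leaves the whole connectome as the third network.
    """
    if c.n_rois != parcels.n_rois:
        raise ValueError(f"connectome has {c.n_rois} nodes, parcel table {parcels.n_rois}")
    half = parcels.half
    m = c.matrix
    left = m[:half, :half].copy()
    right = m[half:, half:].copy()
    if inter_network == "full":
        inter = m.copy()
    else:
        inter = m.copy()
        inter[:half, :half] = 0.0
        inter[half:, half:] = 0.0
    return HemiNetworks(left=left, right=right, inter=inter)


def threshold_graph(net: np.ndarray, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Keep edges with weight >= tau (diagonal excluded).

    Returns the binary adjacency (for degree and betweenness) and the
    retained-weight matrix (for strength).
    """
    if not 0 < tau < 1:
        raise ValueError(f"threshold {tau} must lie strictly inside (0, 1)")
    net = np.asarray(net, dtype=float)
    adj = net >= tau
    np.fill_diagonal(adj, False)
    weights = np.where(adj, net, 0.0)
    return adj, weights


def _betweenness(adj: np.ndarray, weights: np.ndarray, mode: str) -> np.ndarray:
    ii, jj = np.nonzero(np.triu(adj, 1))
    n = adj.shape[0]
    if ii.size == 0:
        return np.zeros(n)
    g = ig.Graph(n=n, edges=list(zip(ii.tolist(), jj.tolist())))
    if mode == "weighted":
        dist = (1.0 / weights[ii, jj]).tolist()
        return np.asarray(g.betweenness(weights=dist), dtype=float)
    return np.asarray(g.betweenness(), dtype=float)


def node_metrics(
    adj: np.ndarray, weights: np.ndarray, betweenness_mode: str = "binary"
) -> dict[str, np.ndarray]:
    """Per-node betweenness, degree, and strength of one thresholded graph.

    Degree counts retained neighbours, strength sums retained edge weights,
    and betweenness is the unnormalized shortest-path betweenness on the
    binary graph (each geodesic pair counted once, ties split fractionally);
    ``betweenness_mode="weighted"`` uses inverse-weight edge lengths instead.
    Isolated nodes score zero on all three.
    """
    return {
        "betweenness": _betweenness(adj, weights, betweenness_mode),
        "degree": adj.sum(axis=1).astype(float),
        "strength": weights.sum(axis=1),
    }


def auc_over_thresholds(curve: np.ndarray, grid: Iterable[float]) -> np.ndarray:
    """Trapezoidal integral of per-node metric curves over the threshold axis.

    ``curve`` has thresholds on the last axis; returns one AUC per node (or a
    scalar for a 1-D curve).
    """
    grid = np.asarray(list(grid), dtype=float)
    curve = np.asarray(curve, dtype=float)
    if curve.shape[-1] != grid.size:
        raise ValueError(f"curve has {curve.shape[-1]} points but grid has {grid.size}")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    return np.trapezoid(curve, grid, axis=-1)


def _network_aucs(
    net: np.ndarray, grid: tuple[float, ...], betweenness_mode: str
) -> dict[str, NodeMetricAUC]:
    n = net.shape[0]
    curves = {m: np.zeros((n, len(grid))) for m in METRICS}
    for k, tau in enumerate(grid):
        adj, weights = threshold_graph(net, tau)
        vals = node_metrics(adj, weights, betweenness_mode)
        for m in METRICS:
            curves[m][:, k] = vals[m]
    return {
        m: NodeMetricAUC(
            metric=m, grid=tuple(grid), curve=curves[m], auc=auc_over_thresholds(curves[m], grid)
        )
        for m in METRICS
    }


def connectome_to_csv(c: Connectome, path) -> None:
    """Dump one subject's connectome as a square CSV (no header)."""
    np.savetxt(path, c.matrix, delimiter=",", fmt="%.10g")


def auc_table(
    aucs: dict[str, dict[str, np.ndarray]], subject_id: str = ""
):
    """Tidy per-node AUC table: subject, roi_id, network_scope, metric, auc."""
    import pandas as pd

    rows = []
    for metric, scopes in aucs.items():
        for scope, vec in scopes.items():
            for i, v in enumerate(vec):
                rows.append(
                    {
                        "subject_id": subject_id,
                        "roi_id": i + 1,
                        "network_scope": scope,
                        "metric": metric,
                        "auc": float(v),
                    }
                )
    return pd.DataFrame(rows)


def node_metric_aucs(
    hemi: HemiNetworks,
    parcels: ParcelTable,
    grid: Iterable[float],
    betweenness_mode: str = "binary",
) -> dict[str, dict[str, np.ndarray]]:
    """Threshold-integrated nodal metrics for all three networks.

    Returns, per metric, two full-length vectors aligned with the parcel
    table: ``within`` (left nodes scored inside the within-left network,
    right nodes inside the within-right network) and ``inter`` (all nodes
    scored in the inter-hemispheric network).
    """
    grid = tuple(float(t) for t in grid)
    half = parcels.half
    left = _network_aucs(hemi.left, grid, betweenness_mode)
    right = _network_aucs(hemi.right, grid, betweenness_mode)
    inter = _network_aucs(hemi.inter, grid, betweenness_mode)
    out: dict[str, dict[str, np.ndarray]] = {}
    for m in METRICS:
        within = np.concatenate([left[m].auc, right[m].auc])
        out[m] = {"within": within, "inter": inter[m].auc.copy()}
    return out
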