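"""Topological characterization of thresholded covariance networks.

The weighted network is swept over a grid of connection densities (default
5%..50% in 5% steps): at each density the weakest positive edges are
discarded until exactly the prescribed fraction of possible edges remains,
and the surviving edges are binarized. On each binary graph the standard
global statistics (mean clustering Cp, characteristic path length Lp, global
efficiency, hierarchy, synchronization) and nodal statistics (clustering,
degree, local efficiency, betweenness centrality) are computed; a metric's
values across the grid are summarized by the trapezoidal area under the
curve (AUC). Small-world normalization (gamma, lambda, sigma) against
degree-preserving nulls lives in :mod:`metacov.null_models`.

Conventions for sparse/disconnected graphs: Lp averages over connected node
pairs only (so it stays finite at low densities), global efficiency counts
disconnected pairs as 0, and a disconnected graph has synchronization 0
(Laplacian algebraic connectivity 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import CovNetwork

__all__ = [
    "BinaryGraph",
    "MetricCurve",
    "threshold_by_density",
    "nodal_metrics",
    "global_metrics",
    "metric_curve",
    "nodal_metric_table",
    "DEFAULT_DENSITY_GRID",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
]

logger = logging.getLogger(__name__)

DEFAULT_DENSITY_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))

GLOBAL_METRICS = ("Cp", "Lp", "Eglob", "hierarchy", "synchronization")
NODAL_METRICS = ("clustering", "degree", "local_efficiency", "betweenness")
NULL_NORMALIZED_METRICS = ("gamma", "lambda", "sigma")


@dataclass
class BinaryGraph:
    """Undirected unweighted graph over the region-table node order."""

    adjacency: np.ndarray
    node_names: list[str] | None = None

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        a = a.astype(bool)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("self-loops are not allowed")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edge_list())
        return g


def threshold_by_density(network: CovNetwork, density: float) -> BinaryGraph:
    """Keep the k = round(density * n(n-1)/2) strongest positive edges, binarized.

    Negative weights are zeroed before ranking (negative correlations carry
    no edge). Ties at the cut are broken deterministically by ascending node
    index pair, so repeated runs give bit-identical graphs. If fewer than k
    strictly positive weights exist the graph is built from all of them and a
    warning is emitted (an empty graph is a warning condition, not an error).
    """
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must be in (0, 1], got {density}")
    w = np.asarray(network.weights, dtype=float).copy()
    n = w.shape[0]
    np.fill_diagonal(w, 0.0)
    w[w < 0] = 0.0
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    n_pairs = vals.size
    k = int(round(density * n_pairs))
    # stable order: weight descending, then (i, j) ascending
    order = np.lexsort((ju, iu, -vals))
    chosen = order[:k]
    chosen = chosen[vals[chosen] > 0]
    if chosen.size < k:
        logger.info(
            "only %d positive weights available for requested density %s (%d edges)",
            chosen.size, density, k,
        )
        warnings.warn(
            "fewer positive weights than requested edges; graph is sparser than requested",
            stacklevel=2,
        )
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[chosen], ju[chosen]] = True
    adj |= adj.T
    return BinaryGraph(adj, list(network.region_names))


# ---------------------------------------------------------------------------
# metric primitives on adjacency matrices
# ---------------------------------------------------------------------------

def _distances(adj: np.ndarray) -> np.ndarray:
    if not adj.any():
        d = np.full(adj.shape, np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    return shortest_path(csr_matrix(adj.astype(np.int8)), method="D", unweighted=True, directed=False)


def _clustering(adj: np.ndarray) -> np.ndarray:
    a = adj.astype(float)
    k = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def _char_path_length(d: np.ndarray) -> float:
    """Mean shortest-path length over connected pairs only; NaN if no pairs."""
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = d[off][np.isfinite(d[off])]
    return float(finite.mean()) if finite.size else float("nan")


def _local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        eloc[i] = _efficiency_from_distances(_distances(sub))
    return eloc


def _betweenness(graph: BinaryGraph) -> np.ndarray:
    bc = nx.betweenness_centrality(graph.to_networkx(), normalized=False)
    return np.array([bc[i] for i in range(graph.n_nodes)])


def _synchronization(adj: np.ndarray) -> float:
    """Laplacian eigenratio lambda_2 / lambda_max; 0 for disconnected graphs."""
    a = adj.astype(float)
    lap = np.diag(a.sum(axis=1)) - a
    eig = np.linalg.eigvalsh(lap)
    lam_max = float(eig[-1])
    lam2 = float(eig[1]) if eig.size > 1 else 0.0
    if lam_max <= 1e-12 or lam2 <= 1e-9:
        return 0.0
    return lam2 / lam_max


def _hierarchy(adj: np.ndarray) -> float:
    """beta from C(k) ~ k^(-beta): minus the log-log slope of clustering on degree.

    Fitted by least squares over nodes with degree >= 2 and positive
    clustering; NaN when fewer than two eligible nodes exist.
    """
    k = adj.sum(axis=1)
    c = _clustering(adj)
    mask = (k >= 2) & (c > 0)
    if mask.sum() < 2:
        return float("nan")
    logk, logc = np.log(k[mask].astype(float)), np.log(c[mask])
    if np.allclose(logk, logk[0]):
        return float("nan")
    slope = np.polyfit(logk, logc, 1)[0]
    return float(-slope)


# ---------------------------------------------------------------------------
# public metric surfaces
# ---------------------------------------------------------------------------

def nodal_metrics(graph: BinaryGraph) -> pd.DataFrame:
    """Per-node clustering, degree, local efficiency and betweenness centrality.

    Clustering is triangles / (k(k-1)/2) with 0 for degree < 2; local
    efficiency is the global efficiency of the neighbor-induced subgraph;
    betweenness counts shortest paths through the node (fractional for ties,
    unnormalized).
    """
    if graph.n_nodes < 3:
        raise ValueError("at least 3 nodes required")
    adj = graph.adjacency
    names = graph.node_names or list(range(graph.n_nodes))
    return pd.DataFrame(
        {
            "node": names,
            "clustering": _clustering(adj),
            "degree": graph.degrees,
            "local_efficiency": _local_efficiency(adj),
            "betweenness": _betweenness(graph),
        }
    )


def global_metrics(graph: BinaryGraph) -> dict[str, float]:
    """Raw global statistics: Cp, Lp, Eglob, hierarchy, synchronization.

    gamma/lambda/sigma require a null ensemble; see
    :func:`metacov.null_models.normalized_small_world`.
    """
    if graph.n_nodes < 3:
        raise ValueError("at least 3 nodes required")
    adj = graph.adjacency
    d = _distances(adj)
    return {
        "Cp": float(_clustering(adj).mean()),
        "Lp": _char_path_length(d),
        "Eglob": _efficiency_from_distances(d),
        "hierarchy": _hierarchy(adj),
        "synchronization": _synchronization(adj),
    }


def _evaluate_metric(
    graph: BinaryGraph, metric: str, n_null, swap_factor, seed, cache: dict | None = None
) -> float:
    """Evaluate one named statistic; ``cache`` shares per-graph intermediates
    (shortest-path distances, the null ensemble) across metrics."""
    if cache is None:
        cache = {}

    def dist():
        if "d" not in cache:
            cache["d"] = _distances(graph.adjacency)
        return cache["d"]

    if metric in ("Cp", "clustering"):
        return float(_clustering(graph.adjacency).mean())
    if metric == "degree":
        return float(graph.degrees.mean())
    if metric == "Lp":
        return _char_path_length(dist())
    if metric == "Eglob":
        return _efficiency_from_distances(dist())
    if metric == "hierarchy":
        return _hierarchy(graph.adjacency)
    if metric == "synchronization":
        return _synchronization(graph.adjacency)
    if metric == "local_efficiency":
        return float(_local_efficiency(graph.adjacency).mean())
    if metric == "betweenness":
        return float(_betweenness(graph).mean())
    if metric in NULL_NORMALIZED_METRICS:
        from .null_models import build_null_ensemble, normalized_small_world

        if "smallworld" not in cache:
            ens = build_null_ensemble(graph, n_null=n_null, swap_factor=swap_factor, seed=seed)
            cache["smallworld"] = normalized_small_world(graph, ensemble=ens)
        gamma, lam, sigma = cache["smallworld"]
        return {"gamma": gamma, "lambda": lam, "sigma": sigma}[metric]
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class MetricCurve:
    """One metric across the density grid, summarized by its trapezoidal AUC."""

    metric: str
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.size != self.values.size:
            raise ValueError("grid and values must have the same length")
        if self.grid.size < 2:
            raise ValueError("AUC is undefined on a single-point grid")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("density grid must be strictly increasing")

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.values, self.grid))


def metric_curves(
    network: CovNetwork,
    metrics: list[str],
    grid=DEFAULT_DENSITY_GRID,
    n_null: int = 100,
    swap_factor: int = 10,
    seed: int = 0,
) -> dict[str, MetricCurve]:
    """Evaluate several named statistics over the grid in one thresholding pass.

    Nodal metric names give the node-averaged value; ``gamma``/``lambda``/
    ``sigma`` are normalized against ``n_null`` degree-preserving rewired
    surrogates (seeded per density for reproducibility). Shared intermediates
    (the binary graph, its distance matrix, the null ensemble) are computed
    once per density.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("AUC is undefined on a single-point grid")
    if np.any(np.diff(grid) <= 0) or grid.min() <= 0 or grid.max() > 1:
        raise ValueError("grid must be strictly increasing within (0, 1]")
    values: dict[str, list[float]] = {m: [] for m in metrics}
    for di, dens in enumerate(grid):
        g = threshold_by_density(network, float(dens))
        cache: dict = {}
        for m in metrics:
            values[m].append(_evaluate_metric(g, m, n_null, swap_factor, seed + di, cache))
    return {m: MetricCurve(m, grid, np.asarray(values[m])) for m in metrics}


def metric_curve(
    network: CovNetwork,
    metric: str,
    grid=DEFAULT_DENSITY_GRID,
    n_null: int = 100,
    swap_factor: int = 10,
    seed: int = 0,
) -> MetricCurve:
    """Evaluate one named statistic at each density of the grid."""
    return metric_curves(network, [metric], grid, n_null, swap_factor, seed)[metric]


def nodal_metric_table(
    network: CovNetwork, grid=DEFAULT_DENSITY_GRID
) -> pd.DataFrame:
    """Long-format table of all nodal metrics at every density of the grid."""
    rows = []
    for dens in np.asarray(grid, dtype=float):
        g = threshold_by_density(network, float(dens))
        nm = nodal_metrics(g)
        nm = nm.melt(id_vars="node", var_name="metric", value_name="value")
        nm.insert(0, "density", float(dens))
        rows.append(nm)
    return pd.concat(rows, ignore_index=True)
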