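"""Degree-preserving null models and small-world normalization.

A binary graph's clustering and path length are only interpretable relative
to random graphs matched in node count, edge count, and degree sequence. The
Maslov-Sneppen procedure builds such surrogates by repeated double-edge
swaps: pick edges (a, b) and (c, d) on four distinct nodes and rewire to
(a, d) and (c, b) whenever neither exists. Each swap preserves every node's
degree exactly.

Normalized statistics: gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>,
sigma = gamma / lambda (small-worldness; sigma > 1 means more clustered than
random at comparable path length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph_metrics import (
    BinaryGraph,
    _char_path_length,
    _clustering,
    _distances,
)

__all__ = ["NullEnsemble", "maslov_sneppen_rewire", "build_null_ensemble", "normalized_small_world"]

logger = logging.getLogger(__name__)

# Community-standard mixing defaults: 10 * |E| successful swaps per surrogate,
# up to 100 * |E| attempts before accepting partial mixing; 100 surrogates.
DEFAULT_SWAP_FACTOR = 10
DEFAULT_N_NULL = 100
ATTEMPT_FACTOR = 100


def maslov_sneppen_rewire(
    graph: BinaryGraph, swap_factor: int = DEFAULT_SWAP_FACTOR, seed: int = 0
) -> BinaryGraph:
    """One degree-preserving randomization of ``graph``.

    Performs ``swap_factor * |E|`` successful double-edge swaps (or stops
    after ``100 * |E|`` attempts, logging the attained count). Graphs that
    admit no swap (e.g. a triangle) are returned unchanged with a logged
    note. Deterministic for a fixed seed.
    """
    edges = graph.edge_list()
    m = len(edges)
    if m < 2:
        logger.info("graph with %d edges admits no double-edge swap; returned unchanged", m)
        return BinaryGraph(graph.adjacency.copy(), graph.node_names)
    rng = np.random.default_rng(seed)
    adj = graph.adjacency.copy()
    target = swap_factor * m
    max_attempts = ATTEMPT_FACTOR * m
    swaps = attempts = 0
    # draw candidate edge pairs (and a random orientation bit for the second
    # edge — a fixed orientation biases the chain and destroys triangles) in
    # batches to keep the loop cheap
    batch = np.empty((0, 3), dtype=np.int64)
    pos = 0
    while swaps < target and attempts < max_attempts:
        if pos >= batch.shape[0]:
            batch = np.column_stack(
                [rng.integers(0, m, size=(4096, 2)), rng.integers(0, 2, size=4096)]
            )
            pos = 0
        e1, e2, flip = batch[pos]
        pos += 1
        attempts += 1
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        # rewire (a,b),(c,d) -> (a,d),(c,b)
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        edges[e1] = (a, d) if a < d else (d, a)
        edges[e2] = (c, b) if c < b else (b, c)
        swaps += 1
    if swaps < target:
        logger.info(
            "partial mixing: %d/%d swaps after %d attempts", swaps, target, attempts
        )
    out = BinaryGraph(adj, graph.node_names)
    out.attained_swaps = swaps  # type: ignore[attr-defined]
    return out


@dataclass
class NullEnsemble:
    """Summary of degree-preserving surrogates of one source graph."""

    source: BinaryGraph
    n_networks: int
    seed: int
    cp_null: np.ndarray = field(default_factory=lambda: np.empty(0))
    lp_null: np.ndarray = field(default_factory=lambda: np.empty(0))
    attained_swaps: list[int] = field(default_factory=list)

    @property
    def mean_cp(self) -> float:
        return float(self.cp_null.mean())

    @property
    def mean_lp(self) -> float:
        return float(np.nanmean(self.lp_null))

    def summary(self) -> dict[str, float]:
        return {
            "density": self.source.density,
            "n_null": self.n_networks,
            "mean_Cp_null": self.mean_cp,
            "sd_Cp_null": float(self.cp_null.std(ddof=1)) if self.n_networks > 1 else 0.0,
            "mean_Lp_null": self.mean_lp,
            "sd_Lp_null": float(np.nanstd(self.lp_null, ddof=1)) if self.n_networks > 1 else 0.0,
        }


def build_null_ensemble(
    graph: BinaryGraph,
    n_null: int = DEFAULT_N_NULL,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
    seed: int = 0,
) -> NullEnsemble:
    """Generate ``n_null`` independent rewired surrogates and record Cp/Lp.

    Every member is asserted to match the source's degree sequence (and hence
    node count, edge count, and density) exactly.
    """
    if n_null < 2:
        raise ValueError("n_null must be at least 2")
    src_degrees = graph.degrees
    ens = NullEnsemble(graph, n_null, seed)
    cps, lps = [], []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_null)
    for i in range(n_null):
        null = maslov_sneppen_rewire(graph, swap_factor, seed=int(child_seeds[i]))
        if not np.array_equal(null.degrees, src_degrees):
            raise AssertionError("null surrogate degree sequence differs from source")
        cps.append(float(_clustering(null.adjacency).mean()))
        lps.append(_char_path_length(_distances(null.adjacency)))
        ens.attained_swaps.append(getattr(null, "attained_swaps", 0))
    ens.cp_null = np.asarray(cps)
    ens.lp_null = np.asarray(lps)
    return ens


def normalized_small_world(
    graph: BinaryGraph,
    n_null: int = DEFAULT_N_NULL,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
    seed: int = 0,
    ensemble: NullEnsemble | None = None,
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) of ``graph`` against its rewired null ensemble.

    Raises if the null ensemble's mean clustering is 0 (gamma undefined: the
    source density admits no triangles in randomized graphs).
    """
    if ensemble is None:
        ensemble = build_null_ensemble(graph, n_null, swap_factor, seed)
    cp = float(_clustering(graph.adjacency).mean())
    lp = _char_path_length(_distances(graph.adjacency))
    if ensemble.mean_cp == 0:
        raise ValueError("null ensemble mean clustering is 0; gamma undefined")
    gamma = cp / ensemble.mean_cp
    lam = lp / ensemble.mean_lp
    sigma = gamma / lam
    return gamma, lam, sigma


def null_summary_table(
    ensembles: list[NullEnsemble],
) -> pd.DataFrame:
    """Per-density null summary: mean/sd of null Cp and Lp plus gamma/lambda/sigma."""
    rows = []
    for ens in ensembles:
        row = ens.summary()
        gamma, lam, sigma = normalized_small_world(ens.source, ensemble=ens)
        row.update({"gamma": gamma, "lambda": lam, "sigma": sigma})
        rows.append(row)
    return pd.DataFrame(rows)
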