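"""Two-group statistics on uptake and on network topology.

Regional uptake is compared with Welch two-sample t-tests, Holm-corrected
over the tested subset (typically the regions showing significant insula
covariance). Network topology is compared with a subject-relabeling
permutation test: each group's covariance network is a single group-level
object, so classical two-sample tests do not apply to its metrics; instead
subjects are repeatedly relabeled into pseudo-groups of the original sizes,
both networks and the metric-AUC difference are recomputed, and a two-sided
permutation p-value is computed as (1 + #{|null| >= |obs|}) / (n_perm + 1).
When the number of distinct relabelings does not exceed n_perm the test
enumerates them exhaustively and the p-value is exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph_metrics import metric_curves
from .network import partial_correlation_matrix

__all__ = [
    "regional_ttests",
    "PermutationResult",
    "permute_network_metric",
    "metric_aucs",
    "seed_edge_contrast",
]

logger = logging.getLogger(__name__)


def regional_ttests(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    regions: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t-test per region, Holm-adjusted over the subset.

    ``regions`` restricts the comparison (and the multiplicity correction) to
    a subset of columns; by default all shared columns are tested. Raises if
    a region has zero variance in both groups (the t statistic is undefined).
    """
    if group_a.shape[0] < 2 or group_b.shape[0] < 2:
        raise ValueError("both groups need at least 2 subjects")
    if list(group_a.columns) != list(group_b.columns):
        raise ValueError("group uptake matrices must share identical region order")
    cols = list(group_a.columns) if regions is None else list(regions)
    missing = [c for c in cols if c not in group_a.columns]
    if missing:
        raise ValueError(f"unknown region(s): {missing}")
    xa = group_a[cols].to_numpy(dtype=float)
    xb = group_b[cols].to_numpy(dtype=float)
    degenerate = [
        c
        for c, va, vb in zip(cols, xa.var(axis=0, ddof=1), xb.var(axis=0, ddof=1))
        if va == 0 and vb == 0
    ]
    if degenerate:
        raise ValueError(f"zero within-group variance in both groups for: {degenerate}")
    t, p = stats.ttest_ind(xa, xb, axis=0, equal_var=False)
    reject, p_holm, _, _ = multipletests(p, alpha=alpha, method="holm")
    return pd.DataFrame(
        {
            "region": cols,
            "mean_a": xa.mean(axis=0),
            "mean_b": xb.mean(axis=0),
            "mean_diff": xa.mean(axis=0) - xb.mean(axis=0),
            "t": t,
            "p": p,
            "p_holm": p_holm,
            "significant": reject,
        }
    )


def metric_aucs(
    uptake: pd.DataFrame,
    metrics: list[str],
    grid,
    shrinkage: float | str = "auto",
    n_null: int = 100,
    swap_factor: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Build the group network and return each metric's AUC over the grid."""
    net = partial_correlation_matrix(uptake, shrinkage=shrinkage)
    curves = metric_curves(net, metrics, grid, n_null=n_null, swap_factor=swap_factor, seed=seed)
    return {m: curves[m].auc for m in metrics}


@dataclass
class PermutationResult:
    """Observed metric-AUC group difference with its permutation null."""

    metric: str
    observed: float
    n_perm: int
    p: float
    exact: bool
    seed: int
    null_mean: float
    null_sd: float
    null_distribution: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def permute_network_metric(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    metric: str | list[str],
    grid,
    n_perm: int = 1000,
    seed: int = 0,
    shrinkage: float | str = "auto",
    n_null: int = 20,
    swap_factor: int = 10,
) -> dict[str, PermutationResult]:
    """Permutation test for group differences in network-metric AUCs.

    The observed statistic is metric-AUC(network(A)) - metric-AUC(network(B));
    the null relabels the pooled subjects into groups of the original sizes.
    Several metrics can be tested in one pass (networks are rebuilt once per
    relabeling). ``n_null`` applies only to null-normalized metrics (gamma,
    lambda, sigma) and is kept small by default because those metrics are
    recomputed inside every permutation.
    """
    metrics = [metric] if isinstance(metric, str) else list(metric)
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    na, nb = group_a.shape[0], group_b.shape[0]
    if na + nb < 6:
        raise ValueError("at least 6 subjects combined required")
    if list(group_a.columns) != list(group_b.columns):
        raise ValueError("group uptake matrices must share identical region order")

    pooled = np.vstack([group_a.to_numpy(dtype=float), group_b.to_numpy(dtype=float)])
    cols = list(group_a.columns)

    def stat(idx_a: np.ndarray) -> dict[str, float]:
        mask = np.zeros(na + nb, dtype=bool)
        mask[idx_a] = True
        da = pd.DataFrame(pooled[mask], columns=cols)
        db = pd.DataFrame(pooled[~mask], columns=cols)
        aucs_a = metric_aucs(da, metrics, grid, shrinkage, n_null, swap_factor, seed)
        aucs_b = metric_aucs(db, metrics, grid, shrinkage, n_null, swap_factor, seed)
        return {m: aucs_a[m] - aucs_b[m] for m in metrics}

    observed = stat(np.arange(na))

    n_distinct = math.comb(na + nb, na)
    exact = n_distinct <= n_perm
    null: dict[str, list[float]] = {m: [] for m in metrics}
    if exact:
        logger.info(
            "n_perm=%d >= %d distinct relabelings; enumerating exhaustively", n_perm, n_distinct
        )
        for combo in combinations(range(na + nb), na):
            d = stat(np.asarray(combo))
            for m in metrics:
                null[m].append(d[m])
        results = {}
        for m in metrics:
            arr = np.asarray(null[m])
            p = float(np.mean(np.abs(arr) >= abs(observed[m]) - 1e-12))
            results[m] = PermutationResult(
                m, observed[m], n_distinct, p, True, seed, float(arr.mean()), float(arr.std(ddof=1)), arr
            )
        return results

    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        idx_a = rng.choice(na + nb, size=na, replace=False)
        d = stat(idx_a)
        for m in metrics:
            null[m].append(d[m])
    results = {}
    for m in metrics:
        arr = np.asarray(null[m])
        p = float((1 + np.sum(np.abs(arr) >= abs(observed[m]) - 1e-12)) / (n_perm + 1))
        results[m] = PermutationResult(
            m, observed[m], n_perm, p, False, seed, float(arr.mean()), float(arr.std(ddof=1)), arr
        )
    return results


def seed_edge_contrast(result_a: pd.DataFrame, result_b: pd.DataFrame) -> pd.DataFrame:
    """Per-region contrast of two seed-edge tables (A = patients, B = controls).

    Expects the full per-region tables (with ``significant`` flags) in
    identical region order; flags edges significant in A but not B.
    """
    if list(result_a["region"]) != list(result_b["region"]):
        raise ValueError("seed-edge tables have mismatched region order")
    return pd.DataFrame(
        {
            "region": result_a["region"].to_numpy(),
            "r_a": result_a["r"].to_numpy(),
            "significant_a": result_a["significant"].to_numpy(),
            "r_b": result_b["r"].to_numpy(),
            "significant_b": result_b["significant"].to_numpy(),
            "a_only": result_a["significant"].to_numpy()
            & ~result_b["significant"].to_numpy(),
        }
    )
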