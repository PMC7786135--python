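"""Group-level metabolic covariance networks.

Two constructions, both over the region-table node order:

* ``partial_correlation_matrix`` — the full n x n network whose entry (i, j)
  is the correlation of regional uptake across subjects after removing the
  linear influence of every other region. With fewer subjects than regions
  the sample covariance is singular, so the correlation matrix is shrunk
  toward the identity with the Schafer-Strimmer analytic intensity (a
  Ledoit-Wolf-style estimator with a diagonal target) before inversion;
  the intensity used is recorded in the network metadata and can be forced,
  including to 0 when n >> p.

* ``seed_correlations`` — plain Pearson correlations between one seed region
  (the insula) and every other node, with two-sided p-values from the exact
  t transform, Bonferroni-gated and sign-filtered downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import RegionTable

__all__ = [
    "CovNetwork",
    "partial_correlation_matrix",
    "shrunk_correlation",
    "seed_correlations",
    "filter_significant_edges",
]


@dataclass
class CovNetwork:
    """Symmetric weighted network of (partial) correlation coefficients."""

    weights: np.ndarray
    region_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        n = len(self.region_names)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} does not match {n} regions")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(w), 1.0):
            raise ValueError("diagonal must be exactly 1")
        off = w[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal weights must lie in [-1, 1]")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def to_csv(self, path, meta_path=None) -> None:
        """Square matrix CSV with region names on both axes; metadata as JSON sidecar."""
        pd.DataFrame(self.weights, index=self.region_names, columns=self.region_names).to_csv(path)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(self.meta, fh, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path, meta_path=None) -> "CovNetwork":
        df = pd.read_csv(path, index_col=0)
        meta = {}
        if meta_path is not None:
            with open(meta_path) as fh:
                meta = json.load(fh)
        return cls(df.to_numpy(), list(df.columns), meta)


def _standardize(uptake: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    x = uptake.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        names = [uptake.columns[i] for i in degenerate]
        raise ValueError(f"constant uptake column(s): {names}")
    z = (x - x.mean(axis=0)) / sd
    return z, list(uptake.columns)


def _schafer_strimmer_intensity(z: np.ndarray) -> float:
    """Analytic shrinkage intensity for a correlation matrix toward the identity.

    lambda* = sum_{i<j} Var_hat(r_ij) / sum_{i<j} r_ij^2, clipped to [0, 1],
    with Var_hat(r_ij) estimated from the empirical variance of the
    cross products of the standardized data.
    """
    n, p = z.shape
    r = (z.T @ z) / (n - 1)
    w_bar = r * (n - 1) / n  # mean over subjects of w_kij = z_ki * z_kj
    # sum over subjects of (z_ki z_kj)^2, without materializing the n x p x p array
    zsq = z**2
    s2 = zsq.T @ zsq
    var_w = (s2 / n - w_bar**2) * n / (n - 1)
    var_r = var_w * n / (n - 1) ** 2
    iu = np.triu_indices(p, k=1)
    denom = float(np.sum(r[iu] ** 2))
    if denom == 0:
        return 1.0
    lam = float(np.sum(var_r[iu]) / denom)
    return float(np.clip(lam, 0.0, 1.0))


def shrunk_correlation(uptake: pd.DataFrame, shrinkage: float | str = "auto") -> tuple[np.ndarray, float]:
    """Sample correlation matrix shrunk toward the identity.

    ``shrinkage="auto"`` uses the analytic Schafer-Strimmer intensity; a float
    in [0, 1] forces that intensity (0 = plain sample correlation). Returns
    (matrix, intensity used).
    """
    z, _ = _standardize(uptake)
    n = z.shape[0]
    r = (z.T @ z) / (n - 1)
    np.fill_diagonal(r, 1.0)
    if shrinkage == "auto":
        lam = _schafer_strimmer_intensity(z)
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"shrinkage must be in [0, 1], got {lam}")
    r_shrunk = (1.0 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)
    return r_shrunk, lam


def partial_correlation_matrix(
    uptake: pd.DataFrame, shrinkage: float | str = "auto"
) -> CovNetwork:
    """Partial-correlation network: each pair controlling for all other regions.

    Computed from the (shrinkage-regularized) correlation matrix R via its
    inverse Omega: rho_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj). Invariant
    to per-region affine rescaling of the input. Requires n_subjects >= 3 and
    no constant columns; with shrinkage 0 the matrix must be invertible
    (n > p in practice).
    """
    if uptake.shape[0] < 3:
        raise ValueError("at least 3 subjects required")
    r_shrunk, lam = shrunk_correlation(uptake, shrinkage)
    omega = np.linalg.inv(r_shrunk)
    d = np.sqrt(np.diag(omega))
    partial = -omega / np.outer(d, d)
    partial = np.clip((partial + partial.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(partial, 1.0)
    meta = {"shrinkage": lam, "n_subjects": int(uptake.shape[0]), "estimator": "shrunk-correlation-inverse"}
    return CovNetwork(partial, list(uptake.columns), meta)


def seed_correlations(uptake: pd.DataFrame, seed: str) -> pd.DataFrame:
    """Pearson r and two-sided p between the seed region and every other node.

    p is from t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom.
    Returns a DataFrame with columns region, r, p in region-table order.
    """
    if seed not in uptake.columns:
        raise ValueError(f"seed region {seed!r} not among uptake columns")
    n = uptake.shape[0]
    if n < 4:
        raise ValueError("at least 4 subjects required for seed correlations")
    x = uptake.to_numpy(dtype=float)
    cols = list(uptake.columns)
    s = cols.index(seed)
    xs = x[:, s]
    if xs.std(ddof=1) == 0:
        raise ValueError(f"seed region {seed!r} has zero variance")
    others = [c for c in cols if c != seed]
    xc = x - x.mean(axis=0)
    denom = np.sqrt((xc**2).sum(axis=0))
    degenerate = [cols[i] for i in np.flatnonzero(denom == 0)]
    if degenerate:
        raise ValueError(f"constant uptake column(s): {degenerate}")
    r_all = (xc.T @ xc[:, s]) / (denom * denom[s])
    r_all = np.clip(r_all, -1.0, 1.0)
    idx = [cols.index(c) for c in others]
    r = r_all[idx]
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 0.0))
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    return pd.DataFrame({"region": others, "r": r, "p": p})


def filter_significant_edges(
    result: pd.DataFrame, alpha: float = 0.05, m: int | None = None
) -> pd.DataFrame:
    """Seed edges surviving Bonferroni correction, positive correlations only.

    Keeps rows with p <= alpha / m and r > 0, ordered by descending r (ties
    broken by input order, i.e. region-table order). ``m`` defaults to the
    number of tests in ``result``. An empty result is valid.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m is None:
        m = len(result)
    if m < 1:
        raise ValueError("m must be at least 1")
    threshold = alpha / m
    keep = result[(result["p"] <= threshold) & (result["r"] > 0)].copy()
    keep = keep.sort_values("r", ascending=False, kind="stable")
    keep["p_bonferroni_threshold"] = threshold
    return keep.reset_index(drop=True)


def seed_result_table(result: pd.DataFrame, alpha: float = 0.05, m: int | None = None) -> pd.DataFrame:
    """Full per-region seed table: r, p, threshold, significance and sign flags."""
    if m is None:
        m = len(result)
    threshold = alpha / m
    out = result.copy()
    out["p_bonferroni_threshold"] = threshold
    out["significant"] = (out["p"] <= threshold) & (out["r"] > 0)
    out["positive"] = out["r"] > 0
    return out
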