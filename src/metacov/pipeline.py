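"""End-to-end orchestration: simulate/extract -> network -> graph -> compare.

A single :class:`PipelineConfig` drives every stage with one global seed, so
a re-run with an identical config reproduces all numeric outputs
bit-identically. Two input modes exist:

* ``synthetic`` — regional uptake matrices are generated directly from the
  two coupling specifications (epileptic-like insula coupling vs.
  near-independent controls);
* ``images`` — per-subject NIfTI volumes listed in a manifest are flipped,
  smoothed, intensity-normalized and reduced to regional means.

Every stage writes plain-text outputs (TSV/CSV/JSON) into the output
directory, and the run report records seeds, the shrinkage intensities
actually used, attained null-model swap counts, and a SHA-256 hash per
output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison, extraction, graph_metrics, network, null_models, synthetic

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "StageError",
    "default_synthetic_config",
    "default_epileptic_coupling",
    "default_control_coupling",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration failed validation before any stage ran."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


# Insula partners of the default epileptic-like generator: opercular,
# temporo-parietal and basal-ganglia regions in which the motivating clinical
# syndrome shows elevated insular covariance. The generator combines strong
# insula-to-partner partial correlations (the hub phenotype) with tight
# partial-correlation coupling inside three small anatomical modules (the
# "excess of local connections" phenotype). Positive definiteness caps how
# strong large uniform partial-correlation cliques can be (rho < 1/(m-1) for
# an m-node clique), which is why the local coupling lives in 4-node modules.
DEFAULT_EPILEPTIC_PARTNERS = (
    "frontal_inf_oper",
    "frontal_inf_tri",
    "supramarginal",
    "angular",
    "temporal_mid",
    "temporal_inf",
    "hippocampus",
    "amygdala",
    "putamen",
    "pallidum",
)

DEFAULT_EPILEPTIC_MODULES = (
    ("frontal_inf_oper", "frontal_inf_tri", "supramarginal", "angular"),
    ("temporal_mid", "temporal_inf", "hippocampus", "amygdala"),
    ("putamen", "pallidum", "caudate", "thalamus"),
)


def default_epileptic_coupling(
    seed: int = 0,
    rho: float = 0.2,
    rho_module: float = 0.2,
    mean_shift: float = -0.05,
    partners=DEFAULT_EPILEPTIC_PARTNERS,
    modules=DEFAULT_EPILEPTIC_MODULES,
) -> synthetic.CouplingSpec:
    """Epileptic-like group generator: strong insula-to-region partial
    correlations, mutually coupled local modules, and mild hypometabolism
    (on the reference-normalized scale: baseline mean 1, between-subject SD
    0.1) in the insula and its partners."""
    edges = [("insula", p, rho) for p in partners]
    for mod in modules:
        edges += [(a, b, rho_module) for i, a in enumerate(mod) for b in mod[i + 1 :]]
    shifted = {"insula", *partners}
    shifts = {name: mean_shift for name in sorted(shifted)}
    return synthetic.CouplingSpec(
        edges=edges, mean_shift=shifts, base_variance=0.01, seed=seed
    )


def default_control_coupling(seed: int = 1) -> synthetic.CouplingSpec:
    """Control-like group generator: regionally independent uptake."""
    return synthetic.CouplingSpec(edges=[], mean_shift={}, base_variance=0.01, seed=seed)


@dataclass
class PipelineConfig:
    out_dir: str = "metacov_out"
    mode: str = "synthetic"  # "synthetic" | "images"
    seed: int = 7

    # synthetic mode
    n_subjects_a: int = synthetic.DEFAULT_GROUP_SIZES[0]
    n_subjects_b: int = synthetic.DEFAULT_GROUP_SIZES[1]
    coupling_rho: float = 0.2
    coupling_rho_module: float = 0.2
    coupling_mean_shift: float = -0.05

    # images mode
    manifest: str | None = None
    labels: str | None = None
    regions: str | None = None

    # preprocessing
    fwhm_mm: float = 5.0
    smooth: bool = True
    reference_region_id: int | None = None

    # network
    shrinkage: float | str = "auto"
    alpha: float = 0.05
    seed_region: str = "insula"

    # graph
    densities: tuple = graph_metrics.DEFAULT_DENSITY_GRID
    n_null: int = 100
    swap_factor: int = 10

    # comparison
    n_perm: int = 1000
    permuted_metrics: tuple = ("Cp", "Lp", "Eglob", "synchronization")

    def validate(self) -> None:
        dens = np.asarray(self.densities, dtype=float)
        if dens.size < 2 or np.any(dens <= 0) or np.any(dens > 1) or np.any(np.diff(dens) <= 0):
            raise ConfigError(
                f"densities must be strictly increasing within (0, 1] with >= 2 points, got {self.densities}"
            )
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.mode not in ("synthetic", "images"):
            raise ConfigError(f"mode must be 'synthetic' or 'images', got {self.mode!r}")
        if self.mode == "images":
            for label in ("manifest", "labels", "regions"):
                path = getattr(self, label)
                if path is None or not Path(path).exists():
                    raise ConfigError(f"{label} path {path!r} does not resolve")
            if self.reference_region_id is None:
                raise ConfigError("images mode requires reference_region_id")
        if self.n_null < 2:
            raise ConfigError("n_null must be at least 2")
        if self.n_perm < 99:
            raise ConfigError("n_perm must be at least 99")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "densities" in raw:
            raw["densities"] = tuple(raw["densities"])
        if "permuted_metrics" in raw:
            raw["permuted_metrics"] = tuple(raw["permuted_metrics"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["densities"] = [float(x) for x in d["densities"]]
        d["permuted_metrics"] = list(d["permuted_metrics"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def default_synthetic_config(seed: int = 7, out_dir: str = "metacov_out") -> PipelineConfig:
    """The default synthetic study: 17 epileptic-like vs 14 control-like
    subjects over the 53-node region table."""
    return PipelineConfig(out_dir=out_dir, seed=seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_inputs(cfg: PipelineConfig, out: Path):
    """Produce (table, uptake_a, uptake_b) either synthetically or from images."""
    if cfg.mode == "synthetic":
        table = synthetic.make_region_table()
        coup_a = default_epileptic_coupling(
            seed=cfg.seed,
            rho=cfg.coupling_rho,
            rho_module=cfg.coupling_rho_module,
            mean_shift=cfg.coupling_mean_shift,
        )
        coup_b = default_control_coupling(seed=cfg.seed + 1)
        uptake_a = synthetic.simulate_uptake(table, cfg.n_subjects_a, coup_a, subject_prefix="ep")
        uptake_b = synthetic.simulate_uptake(table, cfg.n_subjects_b, coup_b, subject_prefix="hc")
    else:
        table = synthetic.RegionTable.from_tsv(cfg.regions)
        manifest = extraction.read_manifest(cfg.manifest)
        import nibabel as nib

        label_volume = np.asarray(nib.load(cfg.labels).get_fdata()).astype(int)
        groups: dict[str, list[extraction.SubjectImage]] = {}
        for row in manifest.itertuples(index=False):
            img = extraction.load_subject_image(row.path, row.subject_id, row.focus_side)
            img = extraction.flip_lr(img)
            if cfg.smooth:
                img = extraction.smooth(img, cfg.fwhm_mm)
            img = extraction.normalize_to_reference(img, label_volume, cfg.reference_region_id)
            groups.setdefault(row.group, []).append(img)
        names = sorted(groups)
        if len(names) != 2:
            raise ConfigError(f"manifest must define exactly 2 groups, got {names}")
        uptake_a = extraction.extract_uptake(groups[names[0]], label_volume, table)
        uptake_b = extraction.extract_uptake(groups[names[1]], label_volume, table)
    table.to_tsv(out / "regions.tsv")
    _write_tsv(uptake_a, out / "uptake_a.tsv", index=True)
    _write_tsv(uptake_b, out / "uptake_b.tsv", index=True)
    return table, uptake_a, uptake_b


def _stage_network(cfg: PipelineConfig, out: Path, uptake_a, uptake_b):
    nets = {}
    seed_tables = {}
    for label, uptake in (("a", uptake_a), ("b", uptake_b)):
        net = network.partial_correlation_matrix(uptake, shrinkage=cfg.shrinkage)
        net.to_csv(out / f"network_{label}.csv", out / f"network_{label}_meta.json")
        res = network.seed_correlations(uptake, cfg.seed_region)
        full = network.seed_result_table(res, alpha=cfg.alpha)
        _write_tsv(full, out / f"seed_edges_{label}.tsv")
        nets[label] = net
        seed_tables[label] = full
    return nets, seed_tables


def _stage_graph(cfg: PipelineConfig, out: Path, nets):
    grid = np.asarray(cfg.densities, dtype=float)
    long_rows = []
    auc_rows = []
    null_tables = {}
    swap_counts = {}
    for label, net in nets.items():
        ensembles = []
        for di, dens in enumerate(grid):
            g = graph_metrics.threshold_by_density(net, float(dens))
            gm = graph_metrics.global_metrics(g)
            ens = null_models.build_null_ensemble(
                g, n_null=cfg.n_null, swap_factor=cfg.swap_factor, seed=cfg.seed + 1000 * di
            )
            gamma, lam, sigma = null_models.normalized_small_world(g, ensemble=ens)
            gm.update({"gamma": gamma, "lambda": lam, "sigma": sigma})
            ensembles.append(ens)
            for metric, value in gm.items():
                long_rows.append(
                    {"group": label, "metric": metric, "density": float(dens), "node": "global", "value": value}
                )
            nm = graph_metrics.nodal_metrics(g)
            for row in nm.itertuples(index=False):
                for metric in graph_metrics.NODAL_METRICS:
                    long_rows.append(
                        {
                            "group": label,
                            "metric": metric,
                            "density": float(dens),
                            "node": row.node,
                            "value": getattr(row, metric),
                        }
                    )
        null_tables[label] = null_models.null_summary_table(ensembles)
        swap_counts[label] = [int(s) for ens in ensembles for s in ens.attained_swaps]
        _write_tsv(null_tables[label], out / f"null_summary_{label}.tsv")

    long_df = pd.DataFrame(long_rows)
    _write_tsv(long_df, out / "metrics_long.tsv")

    # trapezoidal AUC summaries per (group, metric, node)
    auc_rows = []
    for (metric, node, group), sub in long_df.groupby(["metric", "node", "group"]):
        sub = sub.sort_values("density")
        auc = float(np.trapezoid(sub["value"].to_numpy(), sub["density"].to_numpy()))
        auc_rows.append({"group": group, "metric": metric, "node": node, "auc": auc})
    auc_df = pd.DataFrame(auc_rows).sort_values(["group", "metric", "node"]).reset_index(drop=True)
    _write_tsv(auc_df, out / "metrics_auc.tsv")
    return long_df, auc_df, swap_counts


def _stage_compare(cfg: PipelineConfig, out: Path, uptake_a, uptake_b, seed_tables):
    sig_regions = list(seed_tables["a"].loc[seed_tables["a"]["significant"], "region"])
    if sig_regions:
        reg = comparison.regional_ttests(uptake_a, uptake_b, regions=sig_regions, alpha=cfg.alpha)
    else:
        reg = comparison.regional_ttests(uptake_a, uptake_b, alpha=cfg.alpha)
    _write_tsv(reg, out / "regional_comparison.tsv")

    perm = comparison.permute_network_metric(
        uptake_a,
        uptake_b,
        list(cfg.permuted_metrics),
        cfg.densities,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        shrinkage=cfg.shrinkage,
    )
    perm_df = pd.DataFrame(
        [
            {
                "metric": m,
                "observed_auc_diff": r.observed,
                "n_perm": r.n_perm,
                "p": r.p,
                "exact": r.exact,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
            }
            for m, r in perm.items()
        ]
    )
    _write_tsv(perm_df, out / "network_permutation.tsv")

    contrast = comparison.seed_edge_contrast(seed_tables["a"], seed_tables["b"])
    _write_tsv(contrast, out / "seed_contrast.tsv")
    return reg, perm_df, contrast


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    report: dict = {"seed": config.seed, "stages": {}}

    def run_stage(name, fn, *args):
        logger.info("stage %s: start", name)
        try:
            result = fn(config, out, *args)
        except (ConfigError,):
            raise
        except Exception as exc:  # propagate with stage context
            raise StageError(name, str(exc)) from exc
        logger.info("stage %s: done", name)
        return result

    table, uptake_a, uptake_b = run_stage("inputs", _stage_inputs)
    nets, seed_tables = run_stage("network", _stage_network, uptake_a, uptake_b)
    report["shrinkage"] = {label: nets[label].meta["shrinkage"] for label in nets}
    _, auc_df, swap_counts = run_stage("graph", _stage_graph, nets)
    report["null_swaps_attained"] = {
        label: {"min": min(v), "max": max(v)} for label, v in swap_counts.items()
    }
    run_stage("compare", _stage_compare, uptake_a, uptake_b, seed_tables)

    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "run_report.json")
    report["outputs"] = {p.name: _sha256(p) for p in files}
    report["n_regions"] = table.n_nodes
    report["group_sizes"] = [int(uptake_a.shape[0]), int(uptake_b.shape[0])]
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
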