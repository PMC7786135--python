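"""Synthetic study data: region tables, two-group uptake matrices, phantoms.

Metabolic covariance networks are group-level objects: edges are correlations
of regional tracer uptake measured *across subjects*. To exercise the full
pipeline without patient data this module generates

* a region catalogue mirroring the left-hemisphere AAL cortical/subcortical
  regions plus the ascending-arousal-network brainstem nuclei (53 network
  nodes by default: 39 neocortical, 6 subcortical, 8 brainstem),
* subjects x regions uptake matrices drawn from a multivariate Gaussian whose
  *partial*-correlation structure is specified edge by edge (the natural
  parameterization, since the downstream network is built from partial
  correlations), and
* simple block phantoms (NIfTI volumes plus an integer label volume) so the
  voxel-level extraction stages can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "RegionTable",
    "CouplingSpec",
    "PhantomSpec",
    "make_region_table",
    "build_precision_matrix",
    "precision_to_partial",
    "simulate_uptake",
    "simulate_phantom",
    "DEFAULT_GROUP_SIZES",
]

# Group sizes of the motivating study design (patients, controls); overridable
# everywhere they are used.
DEFAULT_GROUP_SIZES = (17, 14)

CATEGORIES = ("neocortical", "subcortical", "brainstem")

# Left-hemisphere AAL cortical regions (cerebellum excluded), 39 entries.
_NEOCORTICAL_NAMES = [
    "precentral", "frontal_sup", "frontal_sup_orb", "frontal_mid",
    "frontal_mid_orb", "frontal_inf_oper", "frontal_inf_tri",
    "frontal_inf_orb", "rolandic_oper", "supp_motor_area", "olfactory",
    "frontal_sup_medial", "frontal_med_orb", "rectus", "insula",
    "cingulum_ant", "cingulum_mid", "cingulum_post", "parahippocampal",
    "calcarine", "cuneus", "lingual", "occipital_sup", "occipital_mid",
    "occipital_inf", "fusiform", "postcentral", "parietal_sup",
    "parietal_inf", "supramarginal", "angular", "precuneus",
    "paracentral_lobule", "heschl", "temporal_sup", "temporal_pole_sup",
    "temporal_mid", "temporal_pole_mid", "temporal_inf",
]

_SUBCORTICAL_NAMES = [
    "hippocampus", "amygdala", "caudate", "putamen", "pallidum", "thalamus",
]

# Harvard ascending-arousal-network brainstem nuclei, 8 entries.
_BRAINSTEM_NAMES = [
    "dorsal_raphe", "median_raphe", "locus_coeruleus", "periaqueductal_gray",
    "parabrachial_complex", "pontis_oralis", "pedunculopontine", "ventral_tegmental",
]

_MIDLINE_NAMES = frozenset(_BRAINSTEM_NAMES)

REFERENCE_NAME = "cerebellum"
REFERENCE_CATEGORY = "reference"


@dataclass(frozen=True)
class Region:
    region_id: int
    name: str
    hemisphere: str
    category: str
    is_seed: bool = False
    is_reference: bool = False


class RegionTable:
    """Ordered catalogue of network nodes (plus an optional reference region).

    The row order of this table fixes the node order of every downstream
    matrix and graph. Exactly one non-reference row is the seed (the insula);
    the reference region (cerebellar grey matter, used only for intensity
    normalization) is never a network node.
    """

    def __init__(self, regions: list[Region]):
        self.regions = list(regions)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        if any(r.region_id <= 0 for r in self.regions):
            raise ValueError("region ids must be positive integers")
        seeds = [r for r in self.regions if r.is_seed]
        if len(seeds) != 1:
            raise ValueError(f"exactly one seed region required, got {len(seeds)}")
        if seeds[0].is_reference:
            raise ValueError("the seed region cannot be the reference region")
        for r in self.nodes:
            if r.category not in CATEGORIES:
                raise ValueError(
                    f"region {r.name!r}: category {r.category!r} not in {CATEGORIES}"
                )

    # -- views -----------------------------------------------------------
    @property
    def nodes(self) -> list[Region]:
        """Network nodes: every non-reference row, in table order."""
        return [r for r in self.regions if not r.is_reference]

    @property
    def node_names(self) -> list[str]:
        return [r.name for r in self.nodes]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def seed(self) -> Region:
        return next(r for r in self.regions if r.is_seed)

    @property
    def reference(self) -> Region | None:
        refs = [r for r in self.regions if r.is_reference]
        return refs[0] if refs else None

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for r in self.nodes:
            counts[r.category] += 1
        return counts

    def index_of(self, name: str) -> int:
        """Position of a node among the network nodes."""
        for i, r in enumerate(self.nodes):
            if r.name == name:
                return i
        raise KeyError(f"no node named {name!r}")

    def __len__(self) -> int:
        return len(self.regions)

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionTable) and self.regions == other.regions

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.region_id for r in self.regions],
                "name": [r.name for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
                "category": [r.category for r in self.regions],
                "is_seed": [int(r.is_seed) for r in self.regions],
                "is_reference": [int(r.is_reference) for r in self.regions],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RegionTable":
        df = pd.read_csv(path, sep="\t")
        regions = [
            Region(
                region_id=int(row.region_id),
                name=str(row.name_col),
                hemisphere=str(row.hemisphere),
                category=str(row.category),
                is_seed=bool(row.is_seed),
                is_reference=bool(row.is_reference),
            )
            for row in df.rename(columns={"name": "name_col"}).itertuples(index=False)
        ]
        return cls(regions)


def _generic_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i + 1}" for i in range(n)]


def make_region_table(
    n_neocortical: int = 39,
    n_subcortical: int = 6,
    n_brainstem: int = 8,
    seed_name: str = "insula",
    with_reference: bool = False,
) -> RegionTable:
    """Build a region table with the requested composition.

    The default composition (39 neocortical + 6 subcortical + 8 brainstem =
    53 nodes) uses the packaged AAL-left / AAN naming lists; other sizes fall
    back to systematic names, except that ``seed_name`` always labels one
    neocortical region. ``with_reference=True`` appends a cerebellar
    reference row (excluded from the network nodes).

    Deterministic: no randomness is involved.
    """
    for label, n in (
        ("n_neocortical", n_neocortical),
        ("n_subcortical", n_subcortical),
        ("n_brainstem", n_brainstem),
    ):
        if not isinstance(n, (int, np.integer)) or n < 1:
            raise ValueError(f"{label} must be a positive integer, got {n!r}")

    if n_neocortical <= len(_NEOCORTICAL_NAMES):
        neo = list(_NEOCORTICAL_NAMES[:n_neocortical])
    else:
        neo = _generic_names("neocortical", n_neocortical)
    if seed_name not in neo:
        neo[0] = seed_name
    sub = (
        list(_SUBCORTICAL_NAMES[:n_subcortical])
        if n_subcortical <= len(_SUBCORTICAL_NAMES)
        else _generic_names("subcortical", n_subcortical)
    )
    stem = (
        list(_BRAINSTEM_NAMES[:n_brainstem])
        if n_brainstem <= len(_BRAINSTEM_NAMES)
        else _generic_names("brainstem", n_brainstem)
    )

    regions: list[Region] = []
    rid = 1
    for name in neo:
        regions.append(
            Region(rid, name, "left", "neocortical", is_seed=(name == seed_name))
        )
        rid += 1
    for name in sub:
        regions.append(Region(rid, name, "left", "subcortical"))
        rid += 1
    for name in stem:
        hemi = "midline" if name in _MIDLINE_NAMES or name.startswith("brainstem") else "left"
        regions.append(Region(rid, name, hemi, "brainstem"))
        rid += 1
    if with_reference:
        regions.append(
            Region(rid, REFERENCE_NAME, "midline", REFERENCE_CATEGORY, is_reference=True)
        )
    return RegionTable(regions)


# ---------------------------------------------------------------------------
# Gaussian uptake simulation parameterized by partial correlations
# ---------------------------------------------------------------------------

@dataclass
class CouplingSpec:
    """Partial-correlation coupling structure of one synthetic group.

    ``edges`` lists (region, region, rho) with rho the *partial* correlation
    in (-1, 1); unlisted pairs have partial correlation 0. ``mean_shift``
    adds to the baseline mean uptake of 1.0 (negative values emulate regional
    hypometabolism on the reference-normalized scale). The implied precision
    matrix must be positive definite; it is validated at build time rather
    than repaired silently.
    """

    edges: list[tuple[str, str, float]] = field(default_factory=list)
    mean_shift: dict[str, float] = field(default_factory=dict)
    base_variance: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.base_variance <= 0:
            raise ValueError("base_variance must be positive")
        for a, b, rho in self.edges:
            if a == b:
                raise ValueError(f"self-coupling {a!r} not allowed")
            if not -1.0 < rho < 1.0:
                raise ValueError(f"partial correlation for ({a}, {b}) must be in (-1, 1), got {rho}")


def build_precision_matrix(table: RegionTable, coupling: CouplingSpec) -> np.ndarray:
    """Precision (inverse-covariance) matrix over the table's network nodes.

    Construction: Omega = I / base_variance on the diagonal, then for each
    specified edge Omega_ij = -rho * sqrt(Omega_ii * Omega_jj), so that the
    partial correlation -Omega_ij / sqrt(Omega_ii * Omega_jj) equals rho
    exactly. Raises if the result is not positive definite, naming the edges.
    """
    names = table.node_names
    idx = {n: i for i, n in enumerate(names)}
    p = len(names)
    omega = np.eye(p) / coupling.base_variance
    for a, b, rho in coupling.edges:
        for name in (a, b):
            if name not in idx:
                raise ValueError(f"edge references unknown region {name!r}")
        i, j = idx[a], idx[b]
        if omega[i, j] != 0.0:
            raise ValueError(f"duplicate edge ({a}, {b})")
        omega[i, j] = omega[j, i] = -rho * np.sqrt(omega[i, i] * omega[j, j])
    eigmin = float(np.linalg.eigvalsh(omega)[0])
    if eigmin <= 0:
        edge_str = ", ".join(f"({a}, {b}, rho={rho})" for a, b, rho in coupling.edges)
        raise ValueError(
            "implied precision matrix is not positive definite "
            f"(min eigenvalue {eigmin:.3g}); offending edges: {edge_str}"
        )
    return omega


def precision_to_partial(omega: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix of a precision matrix: -Omega_ij / sqrt(Omega_ii Omega_jj)."""
    d = np.sqrt(np.diag(omega))
    partial = -omega / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    return partial


def simulate_uptake(
    table: RegionTable,
    n_subjects: int,
    coupling: CouplingSpec,
    subject_prefix: str = "sub",
) -> pd.DataFrame:
    """Sample an uptake matrix (subjects x network nodes) for one group.

    Rows are i.i.d. draws from N(mu, Omega^-1) where Omega encodes the
    CouplingSpec's partial correlations and mu = 1 + mean_shift per region.
    Reproducible for a fixed ``coupling.seed``.
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be at least 3")
    omega = build_precision_matrix(table, coupling)
    sigma = np.linalg.inv(omega)
    names = table.node_names
    mu = np.ones(len(names))
    for name, shift in coupling.mean_shift.items():
        if name not in names:
            raise ValueError(f"mean_shift references unknown region {name!r}")
        mu[names.index(name)] += shift
    rng = np.random.default_rng(coupling.seed)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n_subjects, len(names)))
    data = mu + z @ chol.T
    index = [f"{subject_prefix}{i + 1:03d}" for i in range(n_subjects)]
    return pd.DataFrame(data, index=pd.Index(index, name="subject_id"), columns=names)


# ---------------------------------------------------------------------------
# Voxel phantoms
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Layout of a block phantom volume.

    Each region occupies a contiguous axis-aligned voxel block of
    ``block_shape``; blocks are laid out on a raster by default, or placed at
    explicit ``block_origins`` (region_id -> (i, j, k)). Blocks are crude
    compared to anatomy but are sufficient to test flipping, smoothing,
    normalization and label-wise averaging.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_noise_sd: float = 0.0
    reference_uptake: float = 1.0
    block_shape: tuple[int, int, int] = (4, 4, 4)
    block_origins: dict[int, tuple[int, int, int]] | None = None
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        if any(int(s) < 1 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if any(int(s) < 1 for s in self.block_shape):
            raise ValueError("block_shape entries must be positive")
        if self.voxel_noise_sd < 0:
            raise ValueError("voxel_noise_sd must be non-negative")


def _raster_origins(spec: PhantomSpec, n_blocks: int) -> list[tuple[int, int, int]]:
    gx, gy, gz = spec.grid_shape
    bx, by, bz = spec.block_shape
    nx, ny, nz = gx // bx, gy // by, gz // bz
    if nx * ny * nz < n_blocks:
        raise ValueError(
            f"grid {spec.grid_shape} holds {nx * ny * nz} blocks of {spec.block_shape}; "
            f"{n_blocks} regions requested"
        )
    origins = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                origins.append((i * bx, j * by, k * bz))
                if len(origins) == n_blocks:
                    return origins
    return origins


def simulate_phantom(
    table: RegionTable,
    uptake_row: np.ndarray,
    spec: PhantomSpec,
) -> tuple[nib.Nifti1Image, nib.Nifti1Image]:
    """Render one subject's uptake row as (image volume, label volume).

    The label volume assigns each region of ``table`` (including the
    reference region, if present) a disjoint voxel block; the image volume is
    the per-region uptake plus i.i.d. Gaussian voxel noise. Returns NIfTI-1
    images whose affine encodes ``spec.voxel_size_mm``, with the first voxel
    axis oriented left-to-right.
    """
    nodes = table.nodes
    uptake_row = np.asarray(uptake_row, dtype=float)
    if uptake_row.shape != (len(nodes),):
        raise ValueError(
            f"uptake_row must have one value per network node ({len(nodes)}), "
            f"got shape {uptake_row.shape}"
        )
    regions = list(table.regions)
    values = {r.region_id: v for r, v in zip(nodes, uptake_row)}
    ref = table.reference
    if ref is not None:
        values[ref.region_id] = spec.reference_uptake

    if spec.block_origins is not None:
        origins = []
        for r in regions:
            if r.region_id not in spec.block_origins:
                raise ValueError(f"block_origins missing region_id {r.region_id}")
            origins.append(tuple(int(v) for v in spec.block_origins[r.region_id]))
    else:
        origins = _raster_origins(spec, len(regions))

    label = np.zeros(spec.grid_shape, dtype=np.int16)
    image = np.zeros(spec.grid_shape, dtype=np.float64)
    bx, by, bz = spec.block_shape
    for r, (ox, oy, oz) in zip(regions, origins):
        if ox + bx > spec.grid_shape[0] or oy + by > spec.grid_shape[1] or oz + bz > spec.grid_shape[2]:
            raise ValueError(f"block for region {r.name!r} exceeds grid {spec.grid_shape}")
        sl = (slice(ox, ox + bx), slice(oy, oy + by), slice(oz, oz + bz))
        if np.any(label[sl] != 0):
            raise ValueError(f"block for region {r.name!r} overlaps a previously placed region")
        label[sl] = r.region_id
        image[sl] = values[r.region_id]

    if spec.voxel_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.voxel_noise_sd, size=image.shape)

    affine = np.diag(list(spec.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(image, affine)
    lab = nib.Nifti1Image(label, affine)
    return img, lab
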