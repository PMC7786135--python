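"""Per-subject image processing and regional uptake extraction.

Turns volumetric tracer images into a subjects x regions uptake matrix:

1. left-right flipping of subjects with a right-sided focus, so all foci lie
   in one hemisphere and group statistics gain sensitivity;
2. isotropic Gaussian smoothing (default 5 mm FWHM);
3. intensity normalization to a reference region (cerebellar grey matter),
   making uptake comparable across subjects;
4. label-wise voxel averaging into one value per region per subject.

Images are assumed to already live in a common space on a shared voxel grid
(the registration/template steps of a full PET pipeline are upstream of this
package); the synthetic phantoms satisfy that by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import RegionTable

__all__ = [
    "SubjectImage",
    "flip_lr",
    "smooth",
    "normalize_to_reference",
    "extract_uptake",
    "read_manifest",
    "load_subject_image",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

FOCUS_SIDES = ("left", "right", "none")


@dataclass(frozen=True)
class SubjectImage:
    """A 3-D image with voxel-size metadata and subject annotations.

    ``affine`` maps voxel indices to world mm; the first voxel axis must be
    the left-right axis for flipping to be meaningful (checked at flip time,
    never guessed).
    """

    data: np.ndarray
    affine: np.ndarray | None
    subject_id: str = ""
    focus_side: str = "none"

    def __post_init__(self):
        if self.focus_side not in FOCUS_SIDES:
            raise ValueError(f"focus_side must be one of {FOCUS_SIDES}, got {self.focus_side!r}")
        if np.asarray(self.data).ndim != 3:
            raise ValueError("data must be a 3-D volume")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id!r}: non-finite voxel values")

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        if self.affine is None:
            raise ValueError(f"subject {self.subject_id!r}: no affine/voxel-size metadata")
        return np.sqrt((np.asarray(self.affine)[:3, :3] ** 2).sum(axis=0))


def load_subject_image(path, subject_id: str = "", focus_side: str = "none") -> SubjectImage:
    img = nib.load(str(path))
    return SubjectImage(
        data=np.asarray(img.get_fdata(), dtype=float),
        affine=np.asarray(img.affine),
        subject_id=subject_id or str(path),
        focus_side=focus_side,
    )


def flip_lr(image: SubjectImage) -> SubjectImage:
    """Mirror the volume along the left-right (first voxel) axis.

    Applied only when ``focus_side == "right"``; left- and no-focus subjects
    pass through unchanged. Output voxel (i, j, k) equals input voxel
    (X-1-i, j, k). The affine must be present and its first voxel axis must
    be the anatomical left-right axis; anything else raises instead of
    silently flipping the wrong axis.
    """
    if image.focus_side != "right":
        return image
    if image.affine is None:
        raise ValueError(
            f"subject {image.subject_id!r}: cannot flip without orientation metadata"
        )
    axcodes = nib.orientations.aff2axcodes(np.asarray(image.affine))
    if axcodes[0] not in ("L", "R"):
        raise ValueError(
            f"subject {image.subject_id!r}: first voxel axis is {axcodes[0]!r}, "
            "expected the left-right axis; conform the image orientation upstream"
        )
    flipped = np.ascontiguousarray(image.data[::-1, :, :])
    return replace(image, data=flipped, focus_side="left")


def smooth(image: SubjectImage, fwhm_mm: float = 5.0) -> SubjectImage:
    """Isotropic Gaussian smoothing with the kernel size given as FWHM in mm.

    sigma (voxels) = fwhm_mm / (2 * sqrt(2 * ln 2)) / voxel_size per axis.
    """
    if fwhm_mm <= 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm}")
    voxel_sizes = image.voxel_sizes_mm  # raises if metadata missing
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_sizes
    smoothed = ndimage.gaussian_filter(np.asarray(image.data, dtype=float), sigma=sigma_vox)
    return replace(image, data=smoothed)


def normalize_to_reference(
    image: SubjectImage, label_volume: np.ndarray, reference_region_id: int
) -> SubjectImage:
    """Divide every voxel by the mean intensity of the reference region.

    After normalization the reference-region mean is exactly 1, putting all
    subjects on a common intensity scale. Raises if the reference region is
    empty or its mean is not strictly positive.
    """
    label_volume = np.asarray(label_volume)
    if label_volume.shape != image.data.shape:
        raise ValueError("label volume shape does not match image shape")
    mask = label_volume == reference_region_id
    if not mask.any():
        raise ValueError(
            f"subject {image.subject_id!r}: reference region {reference_region_id} "
            "has no voxels in the label volume"
        )
    ref_mean = float(np.asarray(image.data)[mask].mean())
    if ref_mean <= 0:
        raise ValueError(
            f"subject {image.subject_id!r}: reference region mean is {ref_mean:.4g}, "
            "must be strictly positive"
        )
    return replace(image, data=np.asarray(image.data, dtype=float) / ref_mean)


def extract_uptake(
    images: list[SubjectImage],
    label_volume: np.ndarray,
    table: RegionTable,
) -> pd.DataFrame:
    """Average voxels per labelled region: one row per subject, one column per node.

    Columns follow the region-table node order; the reference region is never
    a column. Raises if any network node has no voxels in the label volume.
    """
    label_volume = np.asarray(label_volume)
    nodes = table.nodes
    node_ids = np.array([r.region_id for r in nodes])
    for r in nodes:
        if not np.any(label_volume == r.region_id):
            raise ValueError(
                f"region {r.name!r} (id {r.region_id}) has no voxels in the label volume"
            )
    rows = []
    ids = []
    for img in images:
        if np.asarray(img.data).shape != label_volume.shape:
            raise ValueError(
                f"subject {img.subject_id!r}: image shape {np.asarray(img.data).shape} "
                f"does not match label volume {label_volume.shape}"
            )
        means = ndimage.mean(np.asarray(img.data, dtype=float), labels=label_volume, index=node_ids)
        rows.append(np.asarray(means, dtype=float))
        ids.append(img.subject_id)
    return pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(nodes))),
        index=pd.Index(ids, name="subject_id"),
        columns=[r.name for r in nodes],
    )


def read_manifest(path) -> pd.DataFrame:
    """Subject manifest TSV with columns subject_id, path, focus_side, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "path", "focus_side", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = set(df["focus_side"]) - set(FOCUS_SIDES)
    if bad:
        raise ValueError(f"manifest has invalid focus_side values: {sorted(bad)}")
    return df
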