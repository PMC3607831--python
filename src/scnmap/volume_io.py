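"""NIfTI volume handling: loading cohorts, coordinate transforms, masks, smoothing.

All volumes in one analysis share a single grid (shape + affine).  Voxel
indices are 0-based; every coordinate reported to the user is MNI mm.  Gray
matter (GM) values are modulated tissue volumes and therefore nonnegative;
NaNs in input images are replaced by zero (and counted in the log) so that
downstream linear algebra never sees non-finite values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("scnmap")

#: conversion between a Gaussian FWHM and its standard deviation
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

REQUIRED_COVARIATE_COLUMNS = ("subject_id", "group", "gender", "age")


class GridMismatchError(ValueError):
    """Raised when an image's geometry disagrees with the cohort grid."""


@dataclass
class GMImage:
    """One subject's 3D gray-matter volume map.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Modulated GM volume per voxel (arbitrary units, nonnegative).
    affine : ndarray, shape (4, 4)
        Voxel-index -> MNI-mm transform; must be invertible.
    subject_id : str
    """

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"GMImage data must be 3D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        n_nan = int(np.count_nonzero(~np.isfinite(self.data)))
        if n_nan:
            logger.warning(
                "image %s: %d non-finite voxels set to 0", self.subject_id, n_nan
            )
            self.data = np.where(np.isfinite(self.data), self.data, 0.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_sizes_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm, from the affine column norms."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class BrainMask:
    """Boolean analysis mask on the cohort grid."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


@dataclass
class Cohort:
    """Ordered collection of GM images on one grid plus a covariate table.

    ``covariates`` has one row per image, in image order, with columns
    ``subject_id``, ``group`` (categorical label), ``gender`` (binary label)
    and ``age`` (years).  Row *i* always corresponds to ``images[i]``; every
    design matrix built downstream relies on that ordering.
    """

    images: list[GMImage]
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("cohort must contain at least one image")
        ref = self.images[0]
        for img in self.images[1:]:
            if img.shape != ref.shape or not np.allclose(img.affine, ref.affine):
                raise GridMismatchError(
                    f"inconsistent geometry for subject {img.subject_id!r}: "
                    f"shape {img.shape} / affine differ from {ref.subject_id!r}"
                )
        cov = self.covariates.reset_index(drop=True)
        for col in REQUIRED_COVARIATE_COLUMNS:
            if col not in cov.columns:
                raise ValueError(f"covariates missing required column {col!r}")
        if len(cov) != len(self.images):
            raise ValueError(
                f"{len(cov)} covariate rows for {len(self.images)} images"
            )
        if cov["group"].isna().any() or cov["gender"].isna().any():
            raise ValueError("missing group/gender values in covariates")
        ids = [img.subject_id for img in self.images]
        if list(cov["subject_id"].astype(str)) != [str(i) for i in ids]:
            raise ValueError("covariate subject_id order does not match images")
        self.covariates = cov

    def __len__(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.images[0].shape

    @property
    def affine(self) -> np.ndarray:
        return self.images[0].affine

    def stack(self, mask: BrainMask | None = None) -> np.ndarray:
        """Stack subject data into an (n_subjects, n_voxels) float64 array.

        With a mask only in-mask voxels are kept, in C order of the grid.
        """
        if mask is None:
            return np.stack([img.data.reshape(-1) for img in self.images]).astype(
                float
            )
        idx = mask.mask.reshape(-1)
        return np.stack(
            [img.data.reshape(-1)[idx] for img in self.images]
        ).astype(float)

    def subset(self, row_indices: np.ndarray) -> "Cohort":
        """Sub-cohort keeping the given covariate-row indices, order preserved."""
        row_indices = np.asarray(row_indices)
        return Cohort(
            images=[self.images[i] for i in row_indices],
            covariates=self.covariates.iloc[row_indices].reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# loading / saving


def load_image(path, subject_id: str = "") -> GMImage:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    return GMImage(data=data, affine=np.asarray(img.affine), subject_id=subject_id)


def save_image(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float)), str(path))


def read_covariates(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    cov = pd.read_csv(path, sep=sep)
    for col in REQUIRED_COVARIATE_COLUMNS:
        if col not in cov.columns:
            raise ValueError(f"covariates file missing required column {col!r}")
    cov["subject_id"] = cov["subject_id"].astype(str)
    return cov


def load_cohort(image_paths, covariates_path) -> Cohort:
    """Load a cohort; image order follows the covariate-table row order.

    ``image_paths`` may be a list (matched positionally to covariate rows
    after checking IDs where derivable) or a dict mapping subject_id to path.
    """
    cov = read_covariates(covariates_path)
    if isinstance(image_paths, dict):
        paths = []
        for sid in cov["subject_id"]:
            if sid not in image_paths:
                raise FileNotFoundError(f"no image supplied for subject {sid!r}")
            paths.append(image_paths[sid])
    else:
        paths = list(image_paths)
        if len(paths) != len(cov):
            missing = len(cov) - len(paths)
            raise ValueError(
                f"covariate table has {len(cov)} rows but {len(paths)} images "
                f"were supplied ({missing:+d} mismatch); first unmatched subject: "
                f"{cov['subject_id'].iloc[min(len(paths), len(cov) - 1)]!r}"
            )
    images = [
        load_image(p, subject_id=sid) for p, sid in zip(paths, cov["subject_id"])
    ]
    return Cohort(images=images, covariates=cov)


# ---------------------------------------------------------------------------
# coordinates


def mni_to_voxel(coord_mm, affine) -> np.ndarray:
    """MNI mm -> fractional 0-based voxel indices (i, j, k)."""
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine is singular")
    hom = np.append(np.asarray(coord_mm, dtype=float), 1.0)
    return np.linalg.solve(affine, hom)[:3]


def voxel_to_mni(ijk, affine) -> np.ndarray:
    """0-based voxel indices (fractional allowed) -> MNI mm."""
    affine = np.asarray(affine, dtype=float)
    hom = np.append(np.asarray(ijk, dtype=float), 1.0)
    return (affine @ hom)[:3]


def grid_coordinates_mm(shape, affine) -> np.ndarray:
    """MNI mm coordinates of every voxel center; shape (*grid, 3)."""
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    return np.einsum("ab,...b->...a", np.asarray(affine, float), vox)[..., :3]


# ---------------------------------------------------------------------------
# smoothing


def fwhm_to_sigma_vox(fwhm_mm: float, voxel_sizes_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for an isotropic FWHM in mm."""
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    return (fwhm_mm / np.asarray(voxel_sizes_mm, dtype=float)) * FWHM_TO_SIGMA


def smooth_gaussian(image: GMImage, fwhm_mm: float) -> GMImage:
    """Isotropic Gaussian smoothing with the given FWHM in mm.

    Anisotropic voxels are handled with per-axis sigmas.  The boundary mode
    is zero-padding (GM maps are zero outside the head), so mass leaks only
    at the image edge; an interior impulse keeps its total sum.
    """
    from scipy.ndimage import gaussian_filter

    sigma = fwhm_to_sigma_vox(fwhm_mm, image.voxel_sizes_mm())
    out = gaussian_filter(image.data.astype(float), sigma=sigma, mode="constant", cval=0.0)
    return GMImage(data=out, affine=image.affine, subject_id=image.subject_id)


def smooth_array(data: np.ndarray, fwhm_mm: float, voxel_sizes_mm) -> np.ndarray:
    """Smoothing on a bare array (same convention as :func:`smooth_gaussian`)."""
    from scipy.ndimage import gaussian_filter

    sigma = fwhm_to_sigma_vox(fwhm_mm, voxel_sizes_mm)
    return gaussian_filter(np.asarray(data, dtype=float), sigma=sigma, mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# masks


def make_gm_mask(cohort: Cohort, threshold: float = 0.1) -> BrainMask:
    """Analysis mask: voxels whose across-subject mean GM exceeds ``threshold``.

    The threshold is on the same (modulated GM) scale as the images.  The
    resulting voxel count is logged; an empty mask is an error because every
    downstream stage needs at least one voxel.
    """
    mean = np.mean([img.data for img in cohort.images], axis=0)
    mask = mean > threshold
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"threshold excludes all voxels (threshold={threshold})")
    logger.info("GM mask: %d voxels above %.4g", n, threshold)
    return BrainMask(mask=mask, affine=cohort.affine)
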